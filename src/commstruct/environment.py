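"""Temperature predictors, NMDS ordination, and environmental vector fitting.

Eight site-level predictors are derived from monthly mean temperatures:
seasonal means MAT (annual), MAuT (autumn), MWT (winter), MST (spring)
and fluctuations ATF, AWTF, WTF, WSTF, where fluctuation is the sample
standard deviation of the window's monthly means (a max-min range option
is available). Beta-diversity matrices are ordinated by two-dimensional
nonmetric multidimensional scaling and each predictor is fitted as a
direction in ordination space (envfit): direction cosines, squared
multiple correlation r2, and a permutation p-value; arrows are scaled to
length sqrt(r2) so weak predictors draw shorter arrows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

logger = logging.getLogger("commstruct")

MONTH_COLUMNS = tuple(f"m{k:02d}" for k in range(1, 13))

#: Season windows (month numbers) for a Northern-Hemisphere wintering study.
DEFAULT_WINDOWS: dict[str, tuple[int, ...]] = {
    "annual": tuple(range(1, 13)),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "autumn_winter": (9, 10, 11, 12, 1, 2),
    "winter_spring": (12, 1, 2, 3, 4, 5),
}

#: predictor -> (window, kind)
PREDICTOR_DEFS: dict[str, tuple[str, str]] = {
    "MAT": ("annual", "mean"), "MAuT": ("autumn", "mean"),
    "MWT": ("winter", "mean"), "MST": ("spring", "mean"),
    "ATF": ("annual", "fluct"), "AWTF": ("autumn_winter", "fluct"),
    "WTF": ("winter", "fluct"), "WSTF": ("winter_spring", "fluct"),
}

MEAN_PREDICTORS = ("MAT", "MAuT", "MWT", "MST")
FLUCTUATION_PREDICTORS = ("ATF", "AWTF", "WTF", "WSTF")


class EnvironmentError_(ValueError):
    pass


def read_climate(path) -> pd.DataFrame:
    """Read a climate CSV with columns site,m01..m12."""
    df = pd.read_csv(path).set_index("site")
    missing = [c for c in MONTH_COLUMNS if c not in df.columns]
    if missing:
        raise EnvironmentError_(f"climate table missing months: {missing}")
    return df[list(MONTH_COLUMNS)].astype(float)


def temperature_predictors(climate: pd.DataFrame,
                           windows: dict[str, tuple[int, ...]] | None = None,
                           fluctuation: str = "sd") -> pd.DataFrame:
    """Derive the 8 temperature predictors from site x month means (degC).

    ``fluctuation="sd"`` uses the sample SD of the window's monthly
    means; ``"range"`` uses max - min.
    """
    windows = dict(DEFAULT_WINDOWS, **(windows or {}))
    if fluctuation not in ("sd", "range"):
        raise EnvironmentError_(f"unknown fluctuation definition {fluctuation!r}")
    cols = {}
    for name, (window, kind) in PREDICTOR_DEFS.items():
        months = windows[window]
        want = [f"m{m:02d}" for m in months]
        miss = [c for c in want if c not in climate.columns]
        if miss:
            raise EnvironmentError_(f"window {window!r} references missing months {miss}")
        block = climate[want].to_numpy(dtype=float)
        if kind == "mean":
            cols[name] = block.mean(axis=1)
        elif fluctuation == "sd":
            cols[name] = block.std(axis=1, ddof=1)
        else:
            cols[name] = block.max(axis=1) - block.min(axis=1)
    return pd.DataFrame(cols, index=climate.index)


@dataclass
class OrdinationResult:
    coords: pd.DataFrame      # site x (axis1, axis2)
    stress: float             # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool


def nmds(d: pd.DataFrame, k: int = 2, n_starts: int = 16,
         seed: int = 0, max_iter: int = 500) -> OrdinationResult:
    """Nonmetric multidimensional scaling of a site distance matrix.

    Kruskal stress-1 is minimized by iterative monotone regression
    (sklearn's SMACOF-based nonmetric MDS) from ``n_starts`` random
    starts; the best configuration is returned with column means removed.
    """
    D = np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise EnvironmentError_("distance matrix must be square and symmetric")
    if np.all(D == 0):
        raise EnvironmentError_("all-zero distance matrix cannot be ordinated")
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                init="random", n_init=n_starts, max_iter=max_iter, eps=1e-9,
                random_state=int(seed) % (2**31), normalized_stress=True)
    X = model.fit_transform(D)
    X = X - X.mean(axis=0, keepdims=True)
    coords = pd.DataFrame(X, index=getattr(d, "index", range(D.shape[0])),
                          columns=[f"axis{i+1}" for i in range(k)])
    return OrdinationResult(coords, float(model.stress_), n_starts,
                            model.n_iter_ < max_iter)


def envfit(ordination: OrdinationResult | pd.DataFrame,
           predictors: pd.DataFrame, n_perm: int = 999,
           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Fit each predictor as a direction in ordination space.

    Per variable: direction cosines of the regression of the centered,
    scaled variable on the ordination coordinates (unit 2-vector),
    r2 = the regression's squared multiple correlation, permutation
    p = (count of permuted r2 >= observed + 1) / (n_perm + 1), and the
    display arrow = direction * sqrt(r2). Zero-variance predictors are
    flagged and skipped.
    """
    coords = ordination.coords if isinstance(ordination, OrdinationResult) else ordination
    missing = sorted(set(coords.index) - set(predictors.index))
    if missing:
        raise EnvironmentError_(f"predictors missing for sites: {missing}")
    X = coords.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    XtX_inv = np.linalg.pinv(X.T @ X)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = X.shape[0]

    rows = []
    for var in predictors.columns:
        y = predictors.loc[coords.index, var].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("predictor %s has zero variance; skipped", var)
            continue
        y = (y - y.mean()) / y.std(ddof=0)

        def fit_r2(yv: np.ndarray) -> tuple[np.ndarray, float]:
            beta = XtX_inv @ (X.T @ yv)
            fitted = X @ beta
            return beta, float(fitted @ fitted) / float(yv @ yv)

        beta, r2 = fit_r2(y)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else np.zeros_like(beta)
        perm_r2 = np.empty(n_perm)
        for i in range(n_perm):
            perm_r2[i] = fit_r2(y[rng.permutation(n)])[1]
        p = (np.sum(perm_r2 >= r2) + 1) / (n_perm + 1)
        arrow = direction * np.sqrt(r2)
        rows.append({"variable": var, "dx": direction[0], "dy": direction[1],
                     "r2": r2, "p": p,
                     "arrow_x": arrow[0], "arrow_y": arrow[1]})
    return pd.DataFrame(rows).set_index("variable")
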