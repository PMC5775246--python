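"""Within-community phylogenetic / functional structure.

Abundance-weighted mean pairwise distance (MPD) and mean nearest taxon
distance (MNTD), a richness-preserving null model drawing species
identities from the pool, and standardized effect sizes

    SES = (X_obs - mean(X_null)) / sd(X_null)

with the sign convention SES(MPD) = -NRI and SES(MNTD) = -NTI: positive
values mean overdispersion, negative mean clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("commstruct")


class AlphaStructureError(ValueError):
    pass


def _present(community: pd.Series) -> pd.Series:
    community = pd.Series(community, dtype=float)
    return community[community > 0]


def mpd(community, dist: pd.DataFrame, weighted: bool = True) -> float:
    """Mean pairwise distance among species present in a community.

    Unweighted: mean of d(i, j) over distinct unordered pairs. Weighted:
    sum_{i != j} d_ij f_i f_j / sum_{i != j} f_i f_j with f the
    within-community relative abundances; self-pairs are excluded.
    Returns NaN (logged) for communities of fewer than 2 species.
    """
    ab = _present(community)
    if len(ab) < 2:
        logger.info("MPD undefined for community with %d species", len(ab))
        return float("nan")
    missing = sorted(set(ab.index) - set(dist.index))
    if missing:
        raise AlphaStructureError(f"species not in distance matrix: {missing}")
    D = dist.loc[ab.index, ab.index].to_numpy(dtype=float)
    if weighted:
        f = (ab / ab.sum()).to_numpy()
        num = f @ D @ f                      # diagonal contributes 0
        den = 1.0 - float(f @ f)             # sum_{i != j} f_i f_j
        return float(num / den)
    iu = np.triu_indices(len(ab), k=1)
    return float(D[iu].mean())


def mntd(community, dist: pd.DataFrame, weighted: bool = True) -> float:
    """Mean nearest taxon distance among species present in a community.

    Per species i, the minimum distance to any *other* present species;
    averaged plainly or weighted by relative abundance.
    """
    ab = _present(community)
    if len(ab) < 2:
        logger.info("MNTD undefined for community with %d species", len(ab))
        return float("nan")
    missing = sorted(set(ab.index) - set(dist.index))
    if missing:
        raise AlphaStructureError(f"species not in distance matrix: {missing}")
    D = dist.loc[ab.index, ab.index].to_numpy(dtype=float).copy()
    np.fill_diagonal(D, np.inf)
    mins = D.min(axis=1)
    if weighted:
        f = (ab / ab.sum()).to_numpy()
        return float(f @ mins)
    return float(mins.mean())


METRICS = {"MPD": mpd, "MNTD": mntd}


def null_richness(community: pd.Series, pool: list[str],
                  rng: np.random.Generator) -> pd.Series:
    """One richness-preserving null community.

    Draws richness-many species uniformly without replacement from the
    pool and reassigns the observed abundance vector to them in random
    order, so only species identity is randomized.
    """
    ab = _present(community)
    k = len(ab)
    if len(pool) < k:
        raise AlphaStructureError(
            f"pool of {len(pool)} smaller than community richness {k}")
    chosen = rng.choice(len(pool), size=k, replace=False)
    values = rng.permutation(ab.to_numpy())
    out = pd.Series(0.0, index=pd.Index(pool, name=community.index.name))
    out.iloc[chosen] = values
    return out


@dataclass
class SESRecord:
    site: str
    metric: str
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    n_null: int


def ses_alpha(comm: pd.DataFrame, dist: pd.DataFrame, metric: str = "MPD",
              n_null: int = 999, seed: int | np.random.Generator = 0,
              weighted: bool = True, trait_space: bool = False) -> pd.DataFrame:
    """Standardized effect size of MPD or MNTD per site.

    The null keeps each site's richness and abundance vector, drawing
    species identities uniformly from the pool (all species with nonzero
    total abundance). SES is undefined (NaN, run continues) where the
    null SD is 0, e.g. a community containing the entire pool. The
    rank-based p is (count of null <= obs + 1) / (n_null + 1).
    """
    if metric not in METRICS:
        raise AlphaStructureError(f"unknown metric {metric!r}")
    fn = METRICS[metric]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = [s for s in comm.columns if comm[s].sum() > 0]
    missing = sorted(set(pool) - set(dist.index))
    if missing:
        raise AlphaStructureError(f"species not in distance matrix: {missing}")
    name = ("trait" if trait_space else "") + metric
    D = dist.loc[pool, pool].to_numpy(dtype=float)
    npool = len(pool)

    records = []
    for site in comm.index:
        ab = comm.loc[site]
        ab = ab[ab > 0]
        k = len(ab)
        obs = fn(comm.loc[site], dist, weighted=weighted)
        if k < 2 or not np.isfinite(obs):
            records.append(SESRecord(site, name, obs, np.nan, np.nan,
                                     np.nan, np.nan, n_null))
            continue
        f = (ab / ab.sum()).to_numpy()
        # vectorized nulls: random species index draws + permuted weights
        nulls = np.empty(n_null)
        for r in range(n_null):
            idx = rng.choice(npool, size=k, replace=False)
            w = rng.permutation(f) if weighted else None
            sub = D[np.ix_(idx, idx)]
            if metric == "MPD":
                if weighted:
                    nulls[r] = (w @ sub @ w) / (1.0 - w @ w)
                else:
                    iu = np.triu_indices(k, k=1)
                    nulls[r] = sub[iu].mean()
            else:
                sub = sub.copy()
                np.fill_diagonal(sub, np.inf)
                mins = sub.min(axis=1)
                nulls[r] = w @ mins if weighted else mins.mean()
        mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
        p = (np.sum(nulls <= obs) + 1) / (n_null + 1)
        if sd > 0:
            ses = (obs - mu) / sd
        else:
            logger.warning("null SD = 0 at site %s; SES undefined", site)
            ses = np.nan
        records.append(SESRecord(str(site), name, obs, mu, sd, ses, p, n_null))

    return pd.DataFrame([vars(r) for r in records]).set_index("site")
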