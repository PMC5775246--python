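"""Community, trait and site tables: reading, validation, regions, Gower.

The community matrix is a sites x species abundance DataFrame; traits are
a species x trait DataFrame (the study's four: wing_mm, beak_mm,
tarsus_mm, mass_g, but any continuous set works); sites carry a decimal
longitude used to assign them to the west / center / east study regions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("commstruct")

TRAIT_COLUMNS = ("wing_mm", "beak_mm", "tarsus_mm", "mass_g")

#: Half-open longitude bins (decimal degrees E) for the three study regions.
REGION_BINS = (("west", 111.0, 113.0), ("center", 113.0, 115.0),
               ("east", 115.0, 117.0))


class CommunityDataError(ValueError):
    """Raised for invalid community / trait / site input."""


def validate_community(comm: pd.DataFrame) -> pd.DataFrame:
    """Validate a sites x species abundance matrix.

    Negative or non-numeric cells and all-zero sites are errors; all-zero
    species columns are dropped with a log message.
    """
    try:
        comm = comm.astype(float)
    except (TypeError, ValueError) as exc:
        raise CommunityDataError(f"non-numeric abundance value: {exc}") from exc
    if comm.isna().any().any():
        r, c = np.argwhere(comm.isna().to_numpy())[0]
        raise CommunityDataError(
            f"missing abundance at site {comm.index[r]!r}, species {comm.columns[c]!r}")
    neg = np.argwhere((comm.to_numpy() < 0))
    if len(neg):
        r, c = neg[0]
        raise CommunityDataError(
            f"negative abundance at site {comm.index[r]!r}, species {comm.columns[c]!r}")
    empty_sites = comm.index[(comm.sum(axis=1) == 0)]
    if len(empty_sites):
        raise CommunityDataError(
            f"site(s) with no individuals: {', '.join(map(str, empty_sites))}")
    zero_cols = comm.columns[(comm.sum(axis=0) == 0)]
    if len(zero_cols):
        logger.info("dropping %d all-zero species column(s): %s",
                    len(zero_cols), ", ".join(map(str, zero_cols)))
        comm = comm.drop(columns=list(zero_cols))
    return comm


def read_community(path) -> pd.DataFrame:
    """Read a community CSV: first column site ID, remaining columns species."""
    comm = pd.read_csv(path, index_col=0)
    return validate_community(comm)


def species_pool(comm: pd.DataFrame) -> list[str]:
    """Species with nonzero total abundance, in column order."""
    return [s for s in comm.columns if comm[s].sum() > 0]


def assign_regions(longitudes: pd.Series) -> pd.Series:
    """Map site longitudes (decimal degrees E) to study regions.

    Bins are half-open: west = [111, 113), center = [113, 115),
    east = [115, 117).
    """
    longitudes = pd.Series(longitudes, dtype=float)
    out = {}
    for site, lon in longitudes.items():
        for name, lo, hi in REGION_BINS:
            if lo <= lon < hi:
                out[site] = name
                break
        else:
            raise CommunityDataError(
                f"site {site!r} longitude {lon} outside study range [111, 117)")
    return pd.Series(out, name="region").reindex(longitudes.index)


def read_sites(path) -> pd.DataFrame:
    """Read site metadata CSV with columns ``site,longitude``; adds region."""
    df = pd.read_csv(path).set_index("site")
    df["region"] = assign_regions(df["longitude"])
    return df


def read_traits(path) -> pd.DataFrame:
    """Read a species x trait CSV (first column species).

    Morphometric values must be finite and strictly positive.
    """
    tr = pd.read_csv(path, index_col=0)
    return validate_traits(tr, require_positive=True)


def validate_traits(traits: pd.DataFrame,
                    require_positive: bool = False) -> pd.DataFrame:
    traits = traits.astype(float)
    if traits.isna().any().any():
        bad = traits.index[traits.isna().any(axis=1)]
        raise CommunityDataError(
            f"missing trait value(s) for: {', '.join(map(str, bad))}")
    if not np.all(np.isfinite(traits.to_numpy())):
        raise CommunityDataError("non-finite trait value")
    if require_positive and (traits.to_numpy() <= 0).any():
        bad = traits.index[(traits <= 0).any(axis=1)]
        raise CommunityDataError(
            f"non-positive trait value(s) for: {', '.join(map(str, bad))}")
    return traits


def gower_matrix(traits: pd.DataFrame, log_mass: bool = False) -> pd.DataFrame:
    """Gower dissimilarity between species on continuous traits.

    d(i, j) = mean over traits of |x_ik - x_jk| / range_k, with range the
    observed max - min per trait, so values lie in [0, 1]. Traits are
    equally weighted and used raw; ``log_mass`` applies log10 to a
    ``mass_g`` column first.
    """
    traits = validate_traits(traits)
    if traits.shape[0] < 2 or traits.shape[1] < 1:
        raise CommunityDataError("Gower needs >= 2 species and >= 1 trait")
    X = traits.copy()
    if log_mass and "mass_g" in X.columns:
        X["mass_g"] = np.log10(X["mass_g"])
    arr = X.to_numpy(dtype=float)
    rng = arr.max(axis=0) - arr.min(axis=0)
    zero = np.flatnonzero(rng == 0)
    if len(zero):
        raise CommunityDataError(
            f"zero observed range for trait(s): "
            f"{', '.join(X.columns[k] for k in zero)}")
    scaled = arr / rng
    d = np.mean(np.abs(scaled[:, None, :] - scaled[None, :, :]), axis=2)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)
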