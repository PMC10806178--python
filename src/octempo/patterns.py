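"""Cross-donor reproducibility filtering and temporal k-means clustering.

Each gene's per-donor trajectory (log2 normalized counts over the sampled
days) is correlated with the cross-donor mean trajectory; genes whose
profile is reproduced (Pearson r above threshold) in enough donors are kept
and their donor-averaged, z-scored profiles are clustered with Euclidean
k-means.  Cluster centroids are labelled with one of eight temporal
archetypes (early/mid/late peak or trough, or a transient excursion).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import CountMatrix
from .de import normalized_counts

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_MIN_DONORS = 6
DEFAULT_K = 8
DEFAULT_N_INIT = 50
# fraction of the start->extremum excursion the endpoint must retrace for a
# profile to count as transient rather than early/mid
TRANSIENT_RETURN_FRAC = 0.5
# plateau tolerance (z units): the peak position is the FIRST timepoint within
# this margin of the extremum, so ramp-and-hold profiles are dated at the ramp
PLATEAU_TOL_Z = 0.1


@dataclass
class DonorProfiles:
    """log2 normalized expression trajectories, per donor and averaged."""

    per_donor: np.ndarray  # genes x donors x timepoints
    mean: pd.DataFrame  # genes x timepoints
    donors: list
    days: list


def donor_profiles(cm: CountMatrix, sf: pd.Series) -> DonorProfiles:
    """Per-gene log2(normalized count + 1) profile for every donor.

    Requires a complete donor x day grid with exactly one sample per cell.
    """
    design = cm.design
    donors = list(pd.unique(design["donor"]))
    days = sorted(design["day"].astype(float).unique())
    norm = normalized_counts(cm, sf)
    log2n = np.log2(norm + 1.0)

    prof = np.empty((cm.n_genes, len(donors), len(days)))
    for di, donor in enumerate(donors):
        for ti, day in enumerate(days):
            mask = (design["donor"] == donor) & (design["day"].astype(float) == day)
            cols = design.index[mask]
            if len(cols) != 1:
                raise ValueError(
                    f"expected exactly one sample for donor {donor!r} day {day:g}, found {len(cols)}"
                )
            prof[:, di, ti] = log2n[cols[0]].to_numpy()
    mean = pd.DataFrame(prof.mean(axis=1), index=cm.genes, columns=[f"day{d:g}" for d in days])
    return DonorProfiles(per_donor=prof, mean=mean, donors=donors, days=days)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row; NaN when either row has zero variance."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac * bc).sum(axis=1) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    return r


def reproducibility_filter(
    profiles: DonorProfiles,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_donors: int = DEFAULT_MIN_DONORS,
) -> tuple[pd.Index, pd.DataFrame]:
    """Keep genes whose trajectory is reproduced across donors.

    A donor passes when the Pearson correlation between its profile and the
    cross-donor mean profile exceeds ``r_threshold`` (strict); a gene is
    kept when at least ``min_donors`` donors pass.  Zero-variance profiles
    give r = NA, which never counts as a pass.
    """
    if profiles.per_donor.shape[2] < 3:
        raise ValueError("Pearson filtering needs >= 3 timepoints")
    mean = profiles.mean.to_numpy()
    records = {}
    n_pass = np.zeros(profiles.per_donor.shape[0], dtype=int)
    for di, donor in enumerate(profiles.donors):
        r = _rowwise_pearson(profiles.per_donor[:, di, :], mean)
        records[f"r_{donor}"] = r
        n_pass += np.where(np.isnan(r), False, r > r_threshold)
    table = pd.DataFrame(records, index=profiles.mean.index)
    table["n_pass"] = n_pass
    table["kept"] = n_pass >= min_donors
    kept = profiles.mean.index[table["kept"].to_numpy()]
    return kept, table


def zscore_profiles(mean_profiles: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores (population sd); zero-variance rows are dropped."""
    vals = mean_profiles.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance profiles excluded from clustering",
            stacklevel=2,
        )
    z = (vals[~flat] - mu[~flat]) / sd[~flat]
    return pd.DataFrame(z, index=mean_profiles.index[~flat], columns=mean_profiles.columns)


def kmeans_cluster(
    mean_profiles: pd.DataFrame,
    k: int = DEFAULT_K,
    n_init: int = DEFAULT_N_INIT,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Euclidean k-means of z-scored donor-mean profiles.

    Returns (assignment, centroids): assignment maps gene -> cluster id
    (1..k) with the archetype label of its cluster; centroids are re-z-scored
    so each has zero mean and unit variance across timepoints.
    """
    z = zscore_profiles(mean_profiles)
    if z.shape[0] < k:
        raise ValueError(f"need at least k={k} genes with non-flat profiles")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    cent = km.cluster_centers_
    cent = (cent - cent.mean(axis=1, keepdims=True)) / cent.std(axis=1, keepdims=True)
    centroids = pd.DataFrame(
        cent, index=pd.Index(range(1, k + 1), name="cluster"), columns=z.columns
    )
    arch = label_archetypes(centroids)
    assignment = pd.DataFrame(
        {"cluster": labels + 1, "archetype": arch.loc[labels + 1].to_numpy()},
        index=z.index,
    )
    return assignment, centroids


def _label_one(c: np.ndarray) -> str:
    """Archetype of one z-scored centroid profile.

    Direction is set by the larger excursion from the starting value; a
    peak (or trough) at the last timepoint is "late"; an interior extremum
    whose endpoint retraces at least half the excursion is "transient",
    otherwise "early" (extremum at the second timepoint) or "mid".
    """
    up_exc = float(c.max() - c[0])
    down_exc = float(c[0] - c.min())
    if up_exc >= down_exc:
        suffix = "up"
        i_ext = int(np.argmax(c >= c.max() - PLATEAU_TOL_Z))
        excursion = c.max() - c[0]
        retraced = c.max() - c[-1]
    else:
        suffix = "down"
        i_ext = int(np.argmax(c <= c.min() + PLATEAU_TOL_Z))
        excursion = c[0] - c.min()
        retraced = c[-1] - c.min()
    if i_ext == len(c) - 1:
        return f"late_{suffix}"
    if excursion > 0 and retraced >= TRANSIENT_RETURN_FRAC * excursion:
        return f"transient_{suffix}"
    return f"early_{suffix}" if i_ext <= 1 else f"mid_{suffix}"


def label_archetypes(centroids: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [_label_one(row) for row in centroids.to_numpy(dtype=float)],
        index=centroids.index,
        name="archetype",
    )
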