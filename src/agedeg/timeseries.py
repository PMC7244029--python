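"""Time-series differential expression for aging transcriptomes.

The input is a genes x (day, replicate) matrix of log2 expression ratios.
Per gene, the replicate median at each day gives a *median profile*; deltas
are taken against the baseline day (day 4 of adulthood by default), and a
gene is differentially expressed when its maximum absolute change from
baseline exceeds a linear fold-change cutoff (2.5 by default; the cutoff can
be recomputed as the 95th percentile of a permutation null in which each
gene's time labels are shuffled independently).  DEG trajectories are then
k-means clustered (k=40, correlation distance) and the cluster centroids are
hierarchically grouped (complete linkage, Euclidean) into three classes
labeled "up", "down" and "others" by the sign of each group's mean
end-minus-baseline change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

__all__ = [
    "ProfileSet",
    "median_profile",
    "call_ts_degs",
    "permutation_fc_cutoff",
    "cluster_and_classify",
    "run_timeseries_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class ProfileSet:
    """Per-gene median trajectories referenced to the baseline day."""

    profile: pd.DataFrame  # genes x days, replicate medians
    delta: pd.DataFrame  # profile minus its baseline column
    max_abs_change: pd.Series  # max_t |delta(t)|, log2 units
    baseline: int


def _days_of(matrix: pd.DataFrame) -> list:
    if isinstance(matrix.columns, pd.MultiIndex):
        return list(pd.unique(matrix.columns.get_level_values(0)))
    return list(matrix.columns)


def median_profile(matrix: pd.DataFrame, baseline=None) -> ProfileSet:
    """Median trajectory per gene and its change from the baseline day.

    ``matrix`` has either a (day, rep) MultiIndex on columns or one column
    per day.  ``baseline`` defaults to the smallest day; it must be one of
    the matrix's days.
    """
    days = _days_of(matrix)
    if len(days) < 3:
        raise ValueError("need >= 3 time points")
    if baseline is None:
        baseline = min(days)
    if baseline not in days:
        raise ValueError(f"baseline day {baseline!r} not among time points {days}")
    if isinstance(matrix.columns, pd.MultiIndex):
        profile = matrix.T.groupby(level=0, sort=False).median().T
    else:
        profile = matrix.copy()
    profile = profile[sorted(days)]
    delta = profile.sub(profile[baseline], axis=0)
    return ProfileSet(
        profile=profile,
        delta=delta,
        max_abs_change=delta.abs().max(axis=1).rename("max_abs_change"),
        baseline=baseline,
    )


def call_ts_degs(profiles: ProfileSet, fc_cutoff: float = 2.5) -> pd.Series:
    """Flag genes whose maximum absolute change exceeds a linear fold cutoff.

    The comparison is strict on the log2 scale: ``max_abs_change >
    log2(fc_cutoff)``, so a gene exactly at the cutoff is not called.
    """
    if not fc_cutoff > 1:
        raise ValueError(f"fc_cutoff must be > 1 (linear scale), got {fc_cutoff}")
    return (profiles.max_abs_change > np.log2(fc_cutoff)).rename("is_deg")


def permutation_fc_cutoff(
    matrix: pd.DataFrame,
    baseline=None,
    n_perm: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> float:
    """Linear fold-change cutoff from a per-gene label-shuffling null.

    For each permutation the time-point labels of every gene's median
    profile are shuffled independently (preserving each gene's marginal
    values while destroying temporal trend), the maximum absolute change
    from the permuted baseline is recomputed, and the pooled distribution's
    ``percentile`` is returned on the linear scale (2**value).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    prof = median_profile(matrix, baseline=baseline).profile.to_numpy()
    g, t = prof.shape
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_perm, g))
    for i in range(n_perm):
        order = np.argsort(rng.random((g, t)), axis=1)
        perm = np.take_along_axis(prof, order, axis=1)
        delta = perm - perm[:, :1]
        pooled[i] = np.abs(delta).max(axis=1)
    q = float(np.percentile(pooled.ravel(), percentile))
    return float(2.0**q)


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores; returns (standardized rows, mask of non-constant rows).

    On standardized rows squared Euclidean distance is an affine function of
    1 - Pearson correlation, so Euclidean k-means on them is k-means under
    correlation distance.
    """
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd.ravel() > 1e-12
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    return z, ok


def cluster_and_classify(
    delta: pd.DataFrame,
    k: int = 40,
    seed: int = 0,
    dead_zone: float = 0.1,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Cluster DEG trajectories and classify them as up / down / others.

    ``delta`` holds baseline-referenced trajectories of the DEGs only.
    k-means (``n_init=10``, correlation distance via row standardization)
    yields ``k`` clusters; the centroids are merged by complete-linkage
    Euclidean hierarchical clustering into ``n_groups`` groups, and each
    group is labeled by the sign of its members' mean end-minus-baseline
    change (|mean| below ``dead_zone`` log2 units -> "others").  Genes with
    constant trajectories (undefined correlation) are assigned to "others"
    without clustering.
    """
    x = delta.to_numpy(dtype=float)
    out = pd.DataFrame(
        {"cluster": np.zeros(len(delta), dtype=int), "class": "others"},
        index=delta.index,
    )
    z, ok = _standardize_rows(x)
    n_ok = int(ok.sum())
    if n_ok == 0:
        return out
    if (~ok).any():
        logger.info("%d constant trajectories assigned to 'others'", int((~ok).sum()))
    if k > n_ok:
        warnings.warn(f"k={k} exceeds the {n_ok} usable trajectories; using k={n_ok}")
        k = n_ok

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    cluster = km.fit_predict(z[ok])
    out.loc[ok, "cluster"] = cluster + 1  # cluster ids are 1-based

    if k > n_groups:
        tree = linkage(km.cluster_centers_, method="complete", metric="euclidean")
        group_of_cluster = fcluster(tree, t=n_groups, criterion="maxclust")
    else:
        group_of_cluster = np.arange(1, k + 1)

    end_change = x[ok][:, -1]  # delta at the last day (baseline delta is 0)
    gene_group = group_of_cluster[cluster]
    labels = {}
    for g in np.unique(gene_group):
        mean_end = end_change[gene_group == g].mean()
        if mean_end > dead_zone:
            labels[g] = "up"
        elif mean_end < -dead_zone:
            labels[g] = "down"
        else:
            labels[g] = "others"
    out.loc[ok, "class"] = [labels[g] for g in gene_group]
    return out


def run_timeseries_pipeline(
    matrix: pd.DataFrame,
    baseline=None,
    fc_cutoff: float | None = 2.5,
    k: int = 40,
    seed: int = 0,
    n_perm: int = 100,
    percentile: float = 95.0,
) -> tuple[pd.DataFrame, dict]:
    """Median profiles -> DEG calls -> cluster-based up/down classification.

    When ``fc_cutoff`` is None the cutoff is recomputed from the permutation
    null (95th percentile by default) instead of using the fixed 2.5.
    Returns a per-gene table (``is_deg``, ``max_abs_change``, ``cluster``,
    ``class``) and a summary dict.
    """
    profiles = median_profile(matrix, baseline=baseline)
    if fc_cutoff is None:
        fc_cutoff = permutation_fc_cutoff(
            matrix, baseline=baseline, n_perm=n_perm, percentile=percentile, seed=seed
        )
        logger.info("permutation-calibrated fold-change cutoff: %.3f", fc_cutoff)
    is_deg = call_ts_degs(profiles, fc_cutoff=fc_cutoff)

    calls = pd.DataFrame(
        {
            "is_deg": is_deg,
            "max_abs_change": profiles.max_abs_change,
            "cluster": 0,
            "class": "",
        },
        index=matrix.index,
    )
    deg_ids = is_deg.index[is_deg]
    if len(deg_ids) > 0:
        classified = cluster_and_classify(profiles.delta.loc[deg_ids], k=k, seed=seed)
        calls.loc[deg_ids, "cluster"] = classified["cluster"]
        calls.loc[deg_ids, "class"] = classified["class"]

    n_up = int((calls["class"] == "up").sum())
    n_down = int((calls["class"] == "down").sum())
    summary = {
        "n_genes": int(len(matrix)),
        "n_deg": int(is_deg.sum()),
        "n_up": n_up,
        "n_down": n_down,
        "n_others": int(is_deg.sum()) - n_up - n_down,
        "fc_cutoff": float(fc_cutoff),
        "baseline": int(profiles.baseline),
        "k": int(k),
        "seed": int(seed),
    }
    return calls, summary
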