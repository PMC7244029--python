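"""Integrative two-group differential-expression testing.

For each probe, two effect statistics are computed between the "low" and
"high" physical-ability groups: the pooled-variance Student t statistic and
the log2 median ratio (difference of group medians on the log2 scale).  The
null distribution of each statistic is estimated empirically by permuting
sample labels (1000 permutations by default, exhaustive when the relabeling
space is small), pooling the statistic across probes and permutations, and
smoothing the pooled sample with a Gaussian kernel density estimate.
Two-tailed empirical p-values are read off the smoothed null around its
median, combined across the two statistics with Stouffer's method
(direction-signed z scores, equal weights), and a probe is called
differentially expressed when it is (I) present, (II) has combined p below
``alpha`` and (III) an absolute log2 fold-change above ``fc_cut`` (0.58,
i.e. 1.5-fold, by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtri
from scipy.stats import norm

from .containers import ExpressionSet
from .preprocess import PresenceMask, call_present, fit_presence_models, quantile_normalize

__all__ = [
    "DEGConfig",
    "NullDistribution",
    "t_statistic",
    "log2_median_ratio",
    "permutation_null",
    "empirical_pvalue",
    "stouffer_combine",
    "call_degs",
    "run_two_group_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGConfig:
    """Thresholds and permutation settings for the two-group test.

    ``fc_cut`` is on the log2 scale; the default 0.58 corresponds to a
    1.5-fold change.  ``fc_statistic`` selects which statistic plays the
    fold-change role in criterion III ("lmr" = log2 median ratio, the
    default, or "mean_diff").  ``center`` selects the reference point for
    the two-tailed empirical p-value ("median" of the null, or "zero").
    """

    B: int = 1000
    alpha: float = 0.05
    fc_cut: float = 0.58
    seed: int = 0
    aggregate: str = "group-all"
    fc_statistic: str = "lmr"
    center: str = "median"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_cut < 0:
            raise ValueError("fc_cut must be >= 0")
        if self.fc_statistic not in ("lmr", "mean_diff"):
            raise ValueError("fc_statistic must be 'lmr' or 'mean_diff'")
        if self.center not in ("median", "zero"):
            raise ValueError("center must be 'median' or 'zero'")


def t_statistic(group_a, group_b):
    """Pooled-variance Student t statistic of A vs B, positive when mean(A) > mean(B).

    Accepts 1-D vectors (one probe) or 2-D arrays (probes x samples); rows
    are probes.  A zero pooled variance yields 0 when the means are equal
    and a signed infinity sentinel otherwise (resolved to the p-value floor
    downstream).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    sentinel = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    t = np.where(se == 0, sentinel, t)
    return t if np.asarray(group_a).ndim > 1 else float(t[0])


def log2_median_ratio(group_a, group_b):
    """median(A) - median(B) on the log2 scale (log2 ratio of linear medians)."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] < 1 or b.shape[1] < 1:
        raise ValueError("each group needs >= 1 value")
    lmr = np.median(a, axis=1) - np.median(b, axis=1)
    return lmr if np.asarray(group_a).ndim > 1 else float(lmr[0])


def _mean_diff(group_a, group_b):
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    return a.mean(axis=1) - b.mean(axis=1)


_STATISTICS = {"t": t_statistic, "lmr": log2_median_ratio, "mean_diff": _mean_diff}


@dataclass
class NullDistribution:
    """Pooled permutation null of one statistic, smoothed by a Gaussian KDE.

    The KDE uses Silverman's bandwidth on the pooled draws and is evaluated
    on a 2,048-point grid spanning the draw range extended by four
    bandwidths; the density is renormalized to integrate to one.
    """

    name: str
    draws: np.ndarray
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    cdf: np.ndarray = field(repr=False)
    center: float = 0.0
    bandwidth: float = 0.0
    n_permutations: int = 0
    exhaustive: bool = False
    seed: int | None = None
    degenerate: bool = False  # all draws identical: no spread to smooth

    GRID_SIZE = 2048

    @classmethod
    def from_draws(
        cls,
        name: str,
        draws: np.ndarray,
        n_permutations: int,
        exhaustive: bool,
        seed: int | None = None,
        center: str = "median",
    ) -> "NullDistribution":
        draws = np.asarray(draws, dtype=float).ravel()
        draws = draws[np.isfinite(draws)]
        if draws.size == 0:
            raise ValueError("empty null sample")
        c = float(np.median(draws)) if center == "median" else 0.0
        sd = draws.std()
        iqr = np.subtract(*np.percentile(draws, [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        if spread == 0:
            # all mass at one point: keep a token grid, flag degenerate
            grid = np.linspace(c - 1.0, c + 1.0, cls.GRID_SIZE)
            density = np.zeros_like(grid)
            cdf = np.where(grid >= c, 1.0, 0.0)
            return cls(name, draws, grid, density, cdf, c, 0.0, n_permutations,
                       exhaustive, seed, degenerate=True)
        h = 0.9 * spread * draws.size ** (-0.2)
        lo, hi = draws.min() - 4 * h, draws.max() + 4 * h
        edges = np.linspace(lo, hi, cls.GRID_SIZE + 1)
        binw = edges[1] - edges[0]
        counts, _ = np.histogram(draws, bins=edges)
        smooth = gaussian_filter1d(counts.astype(float), sigma=h / binw, mode="constant")
        grid = 0.5 * (edges[:-1] + edges[1:])
        density = smooth / (draws.size * binw)
        area = np.trapezoid(density, grid)
        density = density / area
        cdf = cumulative_trapezoid(density, grid, initial=0.0)
        return cls(name, draws, grid, density, cdf, c, float(h), n_permutations,
                   exhaustive, seed)

    def integral(self) -> float:
        """Total mass of the smoothed density (should be 1)."""
        if self.degenerate:
            return 1.0
        return float(np.trapezoid(self.density, self.grid))

    def cdf_at(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.grid, self.cdf, left=0.0, right=1.0)


def _relabelings(n_samples: int, n_a: int, B: int, seed: int):
    """Index sets for group A under permutation; exhaustive when the space is small."""
    total = comb(n_samples, n_a)
    if total <= B:
        return [np.array(c) for c in combinations(range(n_samples), n_a)], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n_samples)[:n_a] for _ in range(B)], False


def permutation_null(
    values,
    labels,
    statistic: str = "t",
    B: int = 1000,
    seed: int = 0,
    group_a: str | None = None,
    center: str = "median",
) -> NullDistribution:
    """Pooled permutation null of a statistic across all probes.

    For each of ``B`` group-size-preserving relabelings (all of them, each
    exactly once, when the relabeling space has at most ``B`` members), the
    statistic is computed for every probe; the probe x permutation values
    are pooled into a single null sample and smoothed by Gaussian KDE.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    a_label = group_a if group_a is not None else uniq[0]
    n_a = int((labels == a_label).sum())
    n = labels.size
    if n_a < 2 or n - n_a < 2:
        raise ValueError("need >= 2 samples per group")
    stat = _STATISTICS[statistic] if isinstance(statistic, str) else statistic

    idx_sets, exhaustive = _relabelings(n, n_a, B, seed)
    all_cols = np.arange(n)
    draws = np.empty((len(idx_sets), x.shape[0]))
    for i, ia in enumerate(idx_sets):
        ib = np.setdiff1d(all_cols, ia, assume_unique=True)
        draws[i] = stat(x[:, ia], x[:, ib])
        if (i + 1) % 200 == 0:
            logger.info("permutation null (%s): %d/%d relabelings", statistic, i + 1, len(idx_sets))
    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "stat")
    return NullDistribution.from_draws(
        name, draws.ravel(), n_permutations=len(idx_sets), exhaustive=exhaustive,
        seed=seed, center=center,
    )


def empirical_pvalue(observed, null: NullDistribution, floor: float = 1e-12) -> np.ndarray:
    """Two-tailed empirical p-value against a smoothed permutation null.

    The p-value is the KDE mass beyond ``center ± |observed - center|``
    where the center is the null median, clamped to ``[floor, 1]``.
    Non-finite observed statistics (zero-variance sentinels) map to the
    floor.
    """
    obs = np.asarray(observed, dtype=float)
    scalar = obs.ndim == 0
    obs = np.atleast_1d(obs)
    p = np.full(obs.shape, floor)
    finite = np.isfinite(obs)
    if null.degenerate:
        p[finite] = np.where(obs[finite] == null.center, 1.0, floor)
    else:
        d = np.abs(obs[finite] - null.center)
        inner = null.cdf_at(null.center + d) - null.cdf_at(null.center - d)
        p[finite] = 1.0 - inner
    p = np.clip(p, floor, 1.0)
    return float(p[0]) if scalar else p


def stouffer_combine(p_a, p_b, sign_a, sign_b):
    """Combine two two-tailed p-values with direction signs (Stouffer, equal weights).

    Each p is mapped to a signed z = Phi^-1(1 - p/2) * sign; the combined
    z is (z_a + z_b)/sqrt(2) and the result is its two-tailed normal
    p-value.  Equal p-values with opposite signs cancel to p = 1.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    scalar = p_a.ndim == 0 and p_b.ndim == 0
    p_a, p_b = np.atleast_1d(p_a), np.atleast_1d(p_b)
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if ((p <= 0) | (p > 1)).any():
            raise ValueError(f"{name} must lie in (0, 1]")
    z_a = ndtri(1.0 - p_a / 2.0) * np.sign(sign_a)
    z_b = ndtri(1.0 - p_b / 2.0) * np.sign(sign_b)
    z = (z_a + z_b) / sqrt(2.0)
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return float(p[0]) if scalar else p


def call_degs(records: pd.DataFrame, config: DEGConfig) -> pd.DataFrame:
    """Apply the three DEG criteria and add a directional ``call`` column.

    A probe is called up (down) when it is present, its combined p-value is
    below ``alpha`` and its log2 fold-change exceeds ``fc_cut`` in absolute
    value with positive (negative) sign; the fold-change comparison is
    strict, so a probe sitting exactly at the cutoff is not called.
    """
    out = records.copy()
    passes = (
        out["present"]
        & (out["p_combined"] < config.alpha)
        & (out["log2fc"].abs() > config.fc_cut)
    )
    out["call"] = np.where(passes & (out["log2fc"] > 0), "up",
                           np.where(passes & (out["log2fc"] < 0), "down", "none"))
    return out


def run_two_group_pipeline(
    eset: ExpressionSet,
    config: DEGConfig = DEGConfig(),
    group_a: str = "low",
    group_b: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full two-group analysis: normalize, present-call, test, combine, call.

    ``group_a`` is the numerator group (statistics are positive when it is
    higher); by convention the "low" physical-ability group is compared
    against "high".  Returns the per-probe record table and a summary dict
    with counts, thresholds and seeds.
    """
    groups = eset.groups
    uniq = list(pd.unique(groups))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 sample groups, got {uniq}")
    if group_a not in uniq:
        group_a = uniq[0]
    if group_b is None:
        group_b = next(g for g in uniq if g != group_a)
    cols_a = eset.samples_in_group(group_a)
    cols_b = eset.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples in each group")

    values = quantile_normalize(eset.values) if config.normalize else eset.values.copy()

    logger.info("fitting presence mixtures for %d samples", values.shape[1])
    models = fit_presence_models(values)
    mask: PresenceMask = call_present(values, models, rule=config.aggregate, groups=groups)

    a = values[cols_a].to_numpy()
    b = values[cols_b].to_numpy()
    obs_t = t_statistic(a, b)
    obs_lmr = log2_median_ratio(a, b)
    log2fc = obs_lmr if config.fc_statistic == "lmr" else _mean_diff(a, b)

    x = values[cols_a + cols_b].to_numpy()
    labels = np.array([group_a] * len(cols_a) + [group_b] * len(cols_b))
    logger.info("estimating permutation nulls (B=%d)", config.B)
    null_t = permutation_null(x, labels, "t", B=config.B, seed=config.seed,
                              group_a=group_a, center=config.center)
    null_lmr = permutation_null(x, labels, "lmr", B=config.B, seed=config.seed + 1,
                                group_a=group_a, center=config.center)

    floor = 1.0 / (config.B * max(eset.n_probes, 1))
    p_t = empirical_pvalue(obs_t, null_t, floor=floor)
    p_lmr = empirical_pvalue(obs_lmr, null_lmr, floor=floor)
    p_comb = stouffer_combine(p_t, p_lmr, np.sign(obs_t), np.sign(obs_lmr))

    records = pd.DataFrame(
        {
            "T": obs_t,
            "lmr": obs_lmr,
            "p_T": p_t,
            "p_lmr": p_lmr,
            "p_combined": p_comb,
            "log2fc": log2fc,
            "present": mask.per_probe.to_numpy(),
        },
        index=eset.probe_ids,
    )
    records = call_degs(records, config)

    n_up = int((records["call"] == "up").sum())
    n_down = int((records["call"] == "down").sum())
    summary = {
        "n_probes": int(eset.n_probes),
        "n_present": int(records["present"].sum()),
        "n_up": n_up,
        "n_down": n_down,
        "percent_deg": 100.0 * (n_up + n_down) / eset.n_probes,
        "group_a": group_a,
        "group_b": group_b,
        "alpha": config.alpha,
        "fc_cut": config.fc_cut,
        "B": config.B,
        "seed": config.seed,
        "exhaustive_null": bool(null_t.exhaustive),
        "p_floor": floor,
    }
    return records, summary
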