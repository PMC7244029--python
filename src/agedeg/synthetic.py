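"""Synthetic data with planted ground truth.

Two generators emulate the statistical structure the analysis assumes:

* :func:`generate_two_group` — a two-group microarray intensity matrix.  Each
  probe draws a baseline log2 intensity from a two-component (absent /
  present) Gaussian, so each sample's intensity histogram is bimodal the way
  background-dominated array data are.  A fraction of the *present* probes
  carries a mean shift of ``±effect_size`` in the "low" physical-ability
  group; everything planted is recorded in a truth table for recovery tests.

* :func:`generate_timeseries` — an aging time-course of log2 expression
  ratios (baseline day = first time point), with planted monotone up/down
  trajectories reaching ``±max_change`` log2 units by the last day and
  i.i.d. replicate noise.

:func:`classify_by_mv` implements the physiological-age split: worms with a
maximum velocity strictly below 0.22 mm/sec (the minimum velocity observed at
day 1 of adulthood) are "low" physical ability, all others "high".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionSet

__all__ = [
    "TwoGroupConfig",
    "TimeSeriesConfig",
    "generate_two_group",
    "generate_timeseries",
    "classify_by_mv",
    "MV_THRESHOLD",
]

#: Maximum-velocity threshold (mm/sec) separating low from high physical ability.
MV_THRESHOLD = 0.22


def _check_fraction(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")


def _check_positive(name: str, x: float) -> None:
    if not x > 0:
        raise ValueError(f"{name} must be > 0, got {x}")


@dataclass(frozen=True)
class TwoGroupConfig:
    """Configuration of the two-group microarray generator.

    Defaults are deliberately small (2,000 probes, 5 samples per group) so
    the full pipeline runs in seconds; the 20,115-gene scale of a real
    whole-genome array is a configuration choice, not a different code path.
    Intensity units are log2 throughout.
    """

    n_probes: int = 2000
    n_per_group: int = 5
    frac_absent: float = 0.3
    absent_mean: float = 6.0
    absent_sd: float = 0.5
    present_mean: float = 10.0
    present_sd: float = 1.5
    frac_deg: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (the t statistic needs a variance)")
        _check_fraction("frac_absent", self.frac_absent)
        _check_fraction("frac_deg", self.frac_deg)
        _check_positive("absent_sd", self.absent_sd)
        _check_positive("present_sd", self.present_sd)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TimeSeriesConfig:
    """Configuration of the aging time-series generator.

    The default day grid runs from day 4 to day 24 of adulthood, the span of
    the aging time course the pipeline re-analyzes.  Values are log2
    expression ratios relative to a common reference, so a flat gene sits at
    zero and a planted "up" gene climbs linearly to ``+max_change``.
    """

    n_genes: int = 500
    time_points: tuple[int, ...] = (4, 8, 12, 16, 20, 24)
    n_replicates: int = 2
    frac_up: float = 0.1
    frac_down: float = 0.1
    max_change: float = 3.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.time_points) < 3:
            raise ValueError("need >= 3 time points")
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValueError("time_points must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        _check_fraction("frac_up", self.frac_up)
        _check_fraction("frac_down", self.frac_down)
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def classify_by_mv(mv_values, threshold: float = MV_THRESHOLD) -> list[str]:
    """Label samples "low" or "high" physical ability from maximum velocity.

    The comparison is strict: ``mv < threshold`` is "low", a velocity exactly
    at the threshold is "high".  Velocities must be non-negative.
    """
    mv = np.asarray(list(mv_values), dtype=float)
    if mv.size and (mv < 0).any():
        bad = mv[mv < 0][0]
        raise ValueError(f"velocities must be >= 0, got {bad}")
    return ["low" if v < threshold else "high" for v in mv]


def generate_two_group(config: TwoGroupConfig) -> tuple[ExpressionSet, pd.DataFrame]:
    """Simulate a two-group log2 intensity matrix with planted effects.

    Returns
    -------
    eset
        :class:`ExpressionSet` with samples annotated by ``group`` ("low" /
        "high") and a maximum-velocity ``mv`` column consistent with the
        group labels under :func:`classify_by_mv`.
    truth
        Per-probe table with columns ``is_present`` (drawn from the present
        component), ``is_deg``, ``direction`` (+1 up in "low", -1 down, 0),
        and ``effect_size`` (log2 units; 0 for non-DEGs).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_probes, config.n_per_group

    probe_ids = pd.Index([f"probe_{i:05d}" for i in range(n)], name="probe_id")
    sample_ids = [f"low_{j + 1}" for j in range(m)] + [f"high_{j + 1}" for j in range(m)]

    n_absent = int(round(config.frac_absent * n))
    is_present = np.ones(n, dtype=bool)
    absent_idx = rng.choice(n, size=n_absent, replace=False)
    is_present[absent_idx] = False

    baseline = np.where(
        is_present,
        rng.normal(config.present_mean, config.present_sd, size=n),
        rng.normal(config.absent_mean, config.absent_sd, size=n),
    )

    present_idx = np.flatnonzero(is_present)
    n_deg = int(round(config.frac_deg * present_idx.size))
    deg_idx = rng.choice(present_idx, size=n_deg, replace=False)
    direction = np.zeros(n, dtype=int)
    direction[deg_idx] = rng.choice([-1, 1], size=n_deg)

    # sample value = probe baseline + group shift + iid noise; with
    # noise_sd=0 the empirical low-minus-high difference is exactly the plant
    shift = np.zeros((n, 2 * m))
    shift[:, :m] = (direction * config.effect_size)[:, None]
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2 * m)) if config.noise_sd > 0 else 0.0
    values = baseline[:, None] + shift + noise

    mv = np.concatenate(
        [
            rng.uniform(0.05, MV_THRESHOLD - 0.01, size=m),
            rng.uniform(MV_THRESHOLD + 0.01, 0.45, size=m),
        ]
    )
    samples = pd.DataFrame(
        {"group": classify_by_mv(mv), "mv": np.round(mv, 4)},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    eset = ExpressionSet(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        samples=samples,
    )
    truth = pd.DataFrame(
        {
            "is_present": is_present,
            "is_deg": direction != 0,
            "direction": direction,
            "effect_size": np.where(direction != 0, config.effect_size, 0.0),
        },
        index=probe_ids,
    )
    return eset, truth


def generate_timeseries(config: TimeSeriesConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an aging time-series log2-ratio matrix with planted trends.

    Returns
    -------
    matrix
        Genes x (day, replicate) DataFrame; columns are a two-level
        MultiIndex ``(day, rep)``.  Planted "up" genes rise linearly from 0
        at the baseline day to ``+max_change`` at the last day (mirrored for
        "down"); flat genes have zero trend.  Replicate noise is i.i.d.
        Gaussian.
    truth
        Per-gene table with ``is_deg``, ``direction`` and ``effect_size``
        (the planted |end-minus-baseline| change, log2 units).
    """
    rng = np.random.default_rng(config.seed)
    n, days, r = config.n_genes, config.time_points, config.n_replicates
    t = len(days)

    gene_ids = pd.Index([f"gene_{i:05d}" for i in range(n)], name="gene_id")

    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    chosen = rng.choice(n, size=n_up + n_down, replace=False)
    direction = np.zeros(n, dtype=int)
    direction[chosen[:n_up]] = 1
    direction[chosen[n_up:]] = -1

    ramp = np.linspace(0.0, 1.0, t)  # monotone from baseline to end
    trend = direction[:, None] * config.max_change * ramp[None, :]

    values = np.repeat(trend, r, axis=1)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=(n, t * r))

    columns = pd.MultiIndex.from_tuples(
        [(day, f"r{k + 1}") for day in days for k in range(r)], names=["day", "rep"]
    )
    matrix = pd.DataFrame(values, index=gene_ids, columns=columns)
    truth = pd.DataFrame(
        {
            "is_deg": direction != 0,
            "direction": direction,
            "effect_size": np.where(direction != 0, config.max_change, 0.0),
        },
        index=gene_ids,
    )
    return matrix, truth
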