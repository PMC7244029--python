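"""Quantile normalization and present/absent probe calling.

Microarray background produces a low-intensity "absent" mode alongside the
"present" mode of genuinely expressed probes.  After quantile normalization,
each sample's log2 intensity distribution is modelled as a two-component
Gaussian mixture fitted by expectation-maximization; the present/absent
cutoff is the crossing point of the two weighted component densities between
the two means.  Probes above the cutoff are called present in that sample,
and per-probe presence is aggregated across samples by a configurable rule
(default: present in every sample of at least one group).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm, rankdata

__all__ = [
    "FitError",
    "PresenceModel",
    "PresenceMask",
    "quantile_normalize",
    "fit_presence_model",
    "fit_presence_models",
    "call_present",
]


class FitError(RuntimeError):
    """Raised when the mixture fit degenerates; carries diagnostics."""


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    The reference distribution is the row-wise mean of the per-column sorted
    values; each column's values are replaced by the reference values at
    their ranks, preserving within-column rank order.  Tied values receive
    the mean of the reference values at their tied rank positions, which
    makes the transform deterministic and idempotent.
    """
    x = values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("quantile normalization requires finite values")
    n, m = x.shape
    if n == 0 or m == 0:
        return values.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


@dataclass(frozen=True)
class PresenceModel:
    """Two-component Gaussian mixture fit for one sample.

    Components are ordered by mean: component 1 is the low-intensity
    "absent" mode, component 2 the "present" mode.  ``cutoff`` is the log2
    intensity where the two weighted densities cross between the means.
    ``fallback`` is True when no crossing exists between the means (the
    midpoint is used instead) or when the fitted mixture is unimodal, i.e.
    the data do not support a present/absent dichotomy.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    cutoff: float
    log_likelihood: float
    n_iter: int
    converged: bool
    fallback: bool

    def density(self, x):
        """Mixture density at x."""
        x = np.asarray(x, dtype=float)
        return self.weights[0] * norm.pdf(x, self.means[0], self.sds[0]) + self.weights[
            1
        ] * norm.pdf(x, self.means[1], self.sds[1])


def _crossing_points(weights, means, sds) -> np.ndarray:
    """Roots of w1*N(x;m1,s1) = w2*N(x;m2,s2), from the log-density quadratic."""
    (w1, w2), (m1, m2), (s1, s2) = weights, means, sds
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + math.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-300:
        if abs(b) < 1e-300:
            return np.array([])
        return np.array([-c / b])
    disc = b * b - 4 * a * c
    if disc < 0:
        return np.array([])
    sq = math.sqrt(disc)
    return np.array(sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)]))


def _mixture_is_bimodal(weights, means, sds) -> bool:
    """True when the mixture density has an interior dip between the means."""
    m1, m2 = means
    if m2 - m1 <= 0:
        return False
    grid = np.linspace(m1, m2, 512)
    dens = weights[0] * norm.pdf(grid, m1, sds[0]) + weights[1] * norm.pdf(grid, m2, sds[1])
    interior_min = dens[1:-1].min()
    return bool(interior_min < min(dens[0], dens[-1]) * (1 - 1e-9))


def fit_presence_model(
    sample_values,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_sd: float = 1e-4,
) -> PresenceModel:
    """Fit a two-component 1-D Gaussian mixture by EM and locate the cutoff.

    Initialization is deterministic: the sample is split at its median and
    each half is moment-matched, so repeated fits are identical without a
    random seed.  Convergence is declared when the relative log-likelihood
    change drops below ``tol`` (at most ``max_iter`` iterations).

    Raises
    ------
    FitError
        If a component collapses (weight or sd underflows) or the input is
        too small / constant to support a two-component fit.
    """
    x = np.asarray(sample_values, dtype=float).ravel()
    if x.size < 10:
        raise FitError(f"need >= 10 values to fit a mixture, got {x.size}")
    if not np.isfinite(x).all():
        raise FitError("non-finite intensities")
    if np.var(x) == 0:
        raise FitError("zero-variance sample: mixture undefined")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    w = np.array([lo.size, hi.size], dtype=float) / x.size
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum([lo.std(), hi.std()], min_sd)

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space for numerical safety
        log_comp = np.stack(
            [np.log(w[k]) + norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
        )
        log_norm = logsumexp(log_comp, axis=0)
        resp = np.exp(log_comp - log_norm)
        ll = float(log_norm.sum())

        nk = resp.sum(axis=1)
        if nk.min() < 1e-8 * x.size:
            raise FitError(
                f"component collapsed at iteration {it}: "
                f"weights={nk / x.size}, means={mu}, sds={sd}"
            )
        w = nk / x.size
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum((resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk, 0.0))
        if sd.min() < min_sd:
            raise FitError(
                f"component sd underflow at iteration {it}: sds={sd}, means={mu}"
            )
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]

    fallback = False
    roots = _crossing_points(w, mu, sd)
    inside = roots[(roots > mu[0]) & (roots < mu[1])] if roots.size else roots
    if inside.size == 0:
        cutoff = float(mu.mean())
        fallback = True
        warnings.warn(
            "no density crossing between component means; using their midpoint "
            f"({cutoff:.3f}) as the presence cutoff",
            stacklevel=2,
        )
    elif inside.size == 1:
        cutoff = float(inside[0])
    else:
        # two crossings between the means: take the one at the density minimum
        dens = w[0] * norm.pdf(inside, mu[0], sd[0]) + w[1] * norm.pdf(inside, mu[1], sd[1])
        cutoff = float(inside[np.argmin(dens)])

    if not _mixture_is_bimodal(tuple(w), tuple(mu), tuple(sd)):
        fallback = True
        warnings.warn(
            "fitted mixture is unimodal: present/absent dichotomy is not "
            "supported by this sample; cutoff flagged as fallback",
            stacklevel=2,
        )

    return PresenceModel(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        cutoff=cutoff,
        log_likelihood=float(ll_prev),
        n_iter=it,
        converged=converged,
        fallback=fallback,
    )


def fit_presence_models(values: pd.DataFrame, **kwargs) -> dict[str, PresenceModel]:
    """Fit one presence mixture per sample (column)."""
    return {str(s): fit_presence_model(values[s].to_numpy(), **kwargs) for s in values.columns}


@dataclass
class PresenceMask:
    """Per-sample and aggregated present calls."""

    per_sample: pd.DataFrame  # boolean, probes x samples
    per_probe: pd.Series  # boolean, aggregated by `rule`
    rule: str


def _aggregate(per_sample: pd.DataFrame, rule: str, groups: pd.Series | None) -> pd.Series:
    if rule == "any":
        return per_sample.any(axis=1)
    if rule == "all":
        return per_sample.all(axis=1)
    if rule.startswith("fraction:"):
        f = float(rule.split(":", 1)[1])
        if not 0 <= f <= 1:
            raise ValueError(f"fraction must be in [0,1], got {f}")
        return per_sample.mean(axis=1) >= f
    if rule == "group-all":
        if groups is None:
            raise ValueError("rule 'group-all' needs sample group labels")
        flags = []
        for g in pd.unique(groups):
            cols = groups.index[groups == g]
            flags.append(per_sample[list(cols)].all(axis=1))
        return pd.concat(flags, axis=1).any(axis=1)
    raise ValueError(f"unknown aggregation rule: {rule!r}")


def call_present(
    values: pd.DataFrame,
    models: dict[str, PresenceModel],
    rule: str = "group-all",
    groups: pd.Series | None = None,
) -> PresenceMask:
    """Apply per-sample cutoffs and aggregate to a per-probe present flag.

    ``rule`` is one of ``"group-all"`` (present in every sample of at least
    one group — a gene reliably detected in one condition is analyzable),
    ``"any"``, ``"all"`` or ``"fraction:<f>"``.
    """
    missing = [s for s in values.columns if str(s) not in models]
    if missing:
        raise ValueError(f"no presence model for samples: {missing[:5]}")
    per_sample = pd.DataFrame(
        {s: values[s] > models[str(s)].cutoff for s in values.columns},
        index=values.index,
    )
    per_probe = _aggregate(per_sample, rule, groups)
    per_probe.name = "present"
    return PresenceMask(per_sample=per_sample, per_probe=per_probe, rule=rule)
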