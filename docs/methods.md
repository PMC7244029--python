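# Methods

This note records the statistical model behind `agedeg`, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not establish.

## Two-group integrative test

### Normalization

Quantile normalization forces every sample (column) onto one common
distribution: the reference is the row-wise mean of the per-column sorted
values, and each column's values are replaced by the reference values at
their ranks. Ties receive the mean of the reference values at their tied
rank positions (by linear interpolation at the average rank), which makes
the transform deterministic and idempotent. Normalization assumes the
samples' true intensity distributions are exchangeable — reasonable for
replicate hybridizations of the same tissue, wrong if one condition globally
shifts expression.

### Present/absent calling

Array intensities mix a background ("absent") mode with an expression
("present") mode. Per sample, a two-component 1-D Gaussian mixture is fitted
by EM with a deterministic initialization (split at the sample median,
moment-match each half), so fits are reproducible without a random seed.
Convergence: relative log-likelihood change below 1e-8 or 500 iterations.
A component whose weight or standard deviation underflows raises a
`FitError` with the offending parameters.

The cutoff is the crossing of the two weighted component densities between
the means — the root of the quadratic obtained from equating the weighted
log densities, restricted to (μ₁, μ₂); with two interior roots the one at
the lower mixture density is used. When no crossing exists between the
means the midpoint (μ₁+μ₂)/2 is used and the model is flagged (`fallback`)
with a warning. The same flag is raised when the fitted mixture is unimodal
(no interior density minimum between the means): a unimodal sample does not
support a present/absent dichotomy, and the flag prevents a silent,
meaningless cutoff.

Per-probe aggregation: a probe is *present* when it exceeds the cutoff in
every sample of at least one group (default rule `group-all`). Rationale: a
gene reliably detected in one condition is analyzable even if off in the
other — which is exactly the situation for strongly regulated genes.
`any`, `all` and `fraction:<f>` rules are available. The mixture is fitted
per sample, not to pooled samples; pooled fitting is not implemented.

### Statistics and empirical nulls

Per probe: the pooled-variance Student t (not Welch) and the log2 median
ratio (difference of group medians on the log2 scale). A zero pooled
variance yields t = 0 when the means agree and a signed-infinity sentinel
otherwise; sentinels map to the p-value floor.

Null distributions are estimated by permuting sample labels, preserving
group sizes: B = 1000 relabelings by default, drawn uniformly; when the
relabeling space C(n, n₁) has at most B members, all are enumerated exactly
once (with 3+3 samples: 20). The statistic is computed for every probe
under every relabeling and all probe × permutation values are pooled into a
single null sample per statistic — one null per data set, not per gene
(per-gene nulls would need far more than 1000 permutations to resolve small
p-values).

The pooled null is smoothed by a Gaussian KDE with Silverman's bandwidth
h = 0.9·min(sd, IQR/1.349)·n^(−1/5), evaluated by binning the draws on a
2,048-point grid spanning the draw range ± 4h and convolving with a
Gaussian kernel (equivalent to an exact KDE up to the bin width, and linear
rather than quadratic in the null size). The density is renormalized to
unit mass; a spread-free null (all draws identical) is flagged degenerate
and handled exactly (p = 1 at the point mass, floor elsewhere).

The two-tailed empirical p-value of an observed statistic is the KDE mass
outside `center ± |observed − center|`, where the center is the null
*median* (configurable to zero; the median makes the test exact under
asymmetric nulls at the cost of a data-dependent reference point).
P-values are clamped to [1/(B·n_probes), 1]; the floor prevents zero
p-values from breaking the normal-quantile transform.

### Combination and calling

Each p is mapped to a direction-signed z = Φ⁻¹(1 − p/2)·sign(statistic) and
combined as z_c = (z_T + z_lmr)/√2 (Stouffer, equal weights — no weighting
is justified for two statistics of the same data); the combined p is the
two-tailed normal tail of z_c. A probe is called up (down) when present,
combined p < α = 0.05, and log2 fold-change > 0.58 (< −0.58); both
threshold comparisons are strict. The fold-change statistic is the log2
median ratio by default (`mean_diff` available). The empirical p-values are
null-calibrated, not multiplicity-adjusted; no FDR step is applied.

**Known limitation — dependence of the combined test.** T and lmr are
computed from the same samples and are strongly correlated (rank
correlation of their z scores ≈ 0.8 at 5 + 5 samples). The unweighted
Stouffer sum therefore has null variance 1 + ρ ≈ 1.8 rather than 1, and the
combined test is liberal: on data with nothing planted, ~14–15% of probes
reach combined p < 0.05 instead of 5%. This is a property of the method
itself, faithfully reproduced, not of the implementation — the *marginal*
empirical p-values are uniform under the null (verified by
Kolmogorov–Smirnov in the test suite), and the practical false-call rate is
curbed by the presence and 1.5-fold criteria rather than by the combined p
alone. Users who need a calibrated combined test should calibrate z_c
against its own permutation null; that variant is deliberately not the
default because it changes the published procedure.

## Time-series procedure

Input: genes × (day, replicate) log2 expression ratios, day 4 of adulthood
as baseline. The replicate median per day gives the median profile;
Δ(t) = profile(t) − profile(baseline), so Δ(baseline) = 0 identically, and
the DEG statistic is max_t |Δ(t)|. A gene is called when this exceeds
log2(2.5) ≈ 1.3219 (strict); 2.5 is the fixed default and can be recomputed
as the 95th percentile of a permutation null in which each gene's
time-point labels are shuffled independently (shuffling the median profile,
not raw replicate columns, so each gene's marginal distribution is
preserved exactly while temporal order is destroyed).

DEG trajectories are clustered by k-means with k = 40 under correlation
distance, implemented by row-standardizing Δ profiles (squared Euclidean
distance on z-scored rows is an affine function of 1 − Pearson r) with 10
restarts and a fixed seed. Constant Δ profiles, whose correlation is
undefined, are assigned to "others" and excluded from clustering; k is
reduced with a warning when fewer usable profiles than k exist. The k
centroids are then hierarchically clustered (complete linkage, Euclidean)
and the tree cut into exactly three groups; each group is labeled by the
sign of its members' mean end-minus-baseline change, with a ±0.1 log2
dead zone mapping to "others". The dead zone and labeling statistic are the
package's choice where several reasonable mappings from 40 clusters to
3 classes exist; both are configurable.

## Concordance

`overlap_table` cross-tabulates two directional gene sets exactly.
`percent_overlap` = 100·(up∩up + down∩down)/denominator; the denominator
defaults to set A's DEG total and can be set to B's or to the union, since
more than one convention is in use and the choice materially changes the
number.

## Synthetic data

The two-group generator draws a per-probe baseline from an absent
N(6, 0.5²) or present N(10, 1.5²) log2-intensity component (30% absent),
adds a ±effect-size shift to the "low" group for a fraction of present
probes (direction random 50/50 to exercise both call directions), and adds
i.i.d. N(0, 0.3²) noise per measurement. Default size is 2,000 probes and
5 samples per group, small enough that the full pipeline runs in seconds;
the published 20,115-gene array scale is a configuration choice. The group
size per array is not documented for the original design, so 5 per group is
a free, fixed choice. Maximum-velocity values are drawn consistently with
the 0.22 mm/sec split so the classification rule is exercised end to end.

The time-series generator plants linear monotone trajectories from 0 to
±3 log2 units across six days (4–24 of adulthood, two replicates per day,
10% up and 10% down) over N(0, 0.3²) replicate noise.

What the generators deliberately do not emulate: probe-level dye and
scanner artifacts, intensity-dependent variance, correlated noise across
probes, non-monotone age trajectories, and missing values. Passing
recovery tests therefore shows the inference machinery is correct under
its own assumptions — not that those assumptions hold on any particular
real data set.

## Problem sizes used in automated checks

Calibration and recovery checks run at 2,000 probes × 10 samples with
B = 200 permutations (20 repeats for the null calibration) and 500 genes ×
6 days for the time series; the mixture-cutoff check uses n = 20,000 draws.
These sizes put Monte-Carlo error well below the asserted tolerances while
keeping the whole suite fast.
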