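"""Two-group statistics, permutation nulls, Stouffer combination, DEG calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import kstest, norm, skew, spearmanr

from agedeg.containers import ExpressionSet
from agedeg.synthetic import TwoGroupConfig, generate_two_group
from agedeg.twogroup import (
    DEGConfig,
    call_degs,
    empirical_pvalue,
    log2_median_ratio,
    permutation_null,
    run_two_group_pipeline,
    stouffer_combine,
    t_statistic,
)


class TestStatistics:
    def test_t_zero_for_identical_groups(self):
        assert t_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_t_pooled_variance_hand_value(self):
        assert t_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.674, abs=1e-3)

    def test_t_antisymmetric(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=4)
        assert t_statistic(a, b) == pytest.approx(-t_statistic(b, a))

    def test_t_zero_variance_sentinels(self):
        assert np.isposinf(t_statistic([2, 2, 2], [1, 1, 1]))
        assert t_statistic([1, 1, 1], [1, 1, 1]) == 0.0

    def test_t_needs_two_per_group(self):
        with pytest.raises(ValueError):
            t_statistic([1.0], [2.0, 3.0])

    def test_lmr_identical_groups_zero(self):
        assert log2_median_ratio([2, 4, 6], [2, 4, 6]) == 0.0

    def test_lmr_hand_value(self):
        assert log2_median_ratio([3, 5, 7], [1, 2, 3]) == 3.0

    def test_lmr_translation_equivariance(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert log2_median_ratio(a + 1.3, b) == pytest.approx(log2_median_ratio(a, b) + 1.3)

    def test_lmr_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log2_median_ratio([], [1.0])


class TestPermutationNull:
    def test_three_vs_three_is_exhaustive_with_twenty_relabelings(self, rng):
        x = rng.normal(size=(10, 6))
        labels = np.array(["low"] * 3 + ["high"] * 3)
        null = permutation_null(x, labels, "t", B=1000, seed=0)
        assert null.exhaustive
        assert null.n_permutations == 20
        assert null.draws.size == 20 * 10

    def test_identical_rows_give_symmetric_lmr_null(self, rng):
        row = rng.normal(size=10)
        x = np.tile(row, (50, 1))
        labels = np.array(["low"] * 5 + ["high"] * 5)
        null = permutation_null(x, labels, "lmr", B=300, seed=1)
        assert abs(skew(null.draws)) < 0.1

    def test_same_seed_reproduces_draws(self, rng):
        x = rng.normal(size=(40, 10))
        labels = np.array(["low"] * 5 + ["high"] * 5)
        n1 = permutation_null(x, labels, "t", B=50, seed=3)
        n2 = permutation_null(x, labels, "t", B=50, seed=3)
        assert np.array_equal(n1.draws, n2.draws)

    def test_density_integrates_to_one(self, rng):
        x = rng.normal(size=(100, 10))
        labels = np.array(["low"] * 5 + ["high"] * 5)
        null = permutation_null(x, labels, "lmr", B=100, seed=2)
        assert null.integral() == pytest.approx(1.0, abs=1e-3)

    def test_invalid_permutation_count_rejected(self, rng):
        x = rng.normal(size=(10, 6))
        labels = np.array(["low"] * 3 + ["high"] * 3)
        with pytest.raises(ValueError):
            permutation_null(x, labels, "t", B=0)


class TestEmpiricalPvalue:
    def _normal_null(self, rng, n=200_000):
        from agedeg.twogroup import NullDistribution

        return NullDistribution.from_draws("z", rng.normal(size=n), n, False)

    def test_p_one_at_null_center(self, rng):
        null = self._normal_null(rng)
        assert empirical_pvalue(null.center, null) == pytest.approx(1.0, abs=1e-6)

    def test_standard_normal_quantile_recovers_alpha(self, rng):
        null = self._normal_null(rng)
        assert empirical_pvalue(1.96, null) == pytest.approx(0.05, abs=0.01)

    def test_monotone_in_distance_from_center(self, rng):
        null = self._normal_null(rng, n=50_000)
        obs = np.linspace(null.center, null.center + 5, 100)
        p = empirical_pvalue(obs, null)
        assert (np.diff(p) <= 1e-12).all()

    def test_infinite_statistic_maps_to_floor(self, rng):
        null = self._normal_null(rng, n=10_000)
        assert empirical_pvalue(np.inf, null, floor=1e-4) == pytest.approx(1e-4)

    def test_exhaustive_null_matches_exceedance_count_ranks(self, rng):
        """KDE p-values and direct exceedance counts order probes identically."""
        x = rng.normal(size=(100, 6))
        labels = np.array(["low"] * 3 + ["high"] * 3)
        obs = t_statistic(x[:, :3], x[:, 3:])
        null = permutation_null(x, labels, "t", B=1000, seed=0)
        assert null.exhaustive
        p_kde = empirical_pvalue(obs, null)
        d = np.abs(obs - null.center)
        null_d = np.abs(null.draws - null.center)
        p_count = np.array([(null_d >= di).mean() for di in d])
        rho = spearmanr(p_kde, p_count).statistic
        assert rho > 0.9999


class TestStouffer:
    def test_uninformative_pvalues_combine_to_one(self):
        assert stouffer_combine(1.0, 1.0, 1, -1) == pytest.approx(1.0)

    def test_two_nominal_pvalues_same_direction(self):
        # z = 1.95996 each -> combined z = 2.77180 -> two-tailed p = 0.005575
        assert stouffer_combine(0.05, 0.05, 1, 1) == pytest.approx(0.005574597, abs=1e-8)

    def test_opposite_directions_cancel(self):
        assert stouffer_combine(0.01, 0.01, 1, -1) == pytest.approx(1.0)

    def test_matches_closed_form_on_grid(self):
        ps = np.array([1e-6, 1e-3, 0.01, 0.05, 0.2, 0.5, 0.9, 1.0])
        for sa in (1, -1):
            for sb in (1, -1):
                pa, pb = np.meshgrid(ps, ps)
                got = stouffer_combine(pa.ravel(), pb.ravel(), sa, sb)
                za = ndtri(1 - pa.ravel() / 2) * sa
                zb = ndtri(1 - pb.ravel() / 2) * sb
                expected = 2 * norm.sf(np.abs(za + zb) / np.sqrt(2))
                assert np.allclose(got, np.clip(expected, np.finfo(float).tiny, 1), atol=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_out_of_range_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            stouffer_combine(bad, 0.5, 1, 1)


class TestCallDegs:
    def _records(self, present, p, fc):
        return pd.DataFrame(
            {"present": [present], "p_combined": [p], "log2fc": [fc]},
            index=["g1"],
        )

    @pytest.mark.parametrize(
        "present,p,fc,expected",
        [
            (True, 0.01, 1.0, "up"),
            (True, 0.01, -1.0, "down"),
            (False, 0.001, 3.0, "none"),  # criterion I gates
            (True, 0.01, 0.58, "none"),  # strict fold-change inequality
            (True, 0.06, 1.0, "none"),  # criterion II
        ],
    )
    def test_three_criteria(self, present, p, fc, expected):
        out = call_degs(self._records(present, p, fc), DEGConfig())
        assert out.loc["g1", "call"] == expected


class TestPipeline:
    def test_sample_order_does_not_change_calls(self):
        cfg = TwoGroupConfig(n_probes=150, frac_deg=0.15, effect_size=3.0, seed=5)
        eset, _ = generate_two_group(cfg)
        deg_cfg = DEGConfig(B=60, seed=4)
        rec1, _ = run_two_group_pipeline(eset, deg_cfg)
        shuffled = ExpressionSet(
            values=eset.values.iloc[:, ::-1], samples=eset.samples.iloc[::-1]
        )
        rec2, _ = run_two_group_pipeline(shuffled, deg_cfg)
        assert (rec1["call"] == rec2["call"]).all()

    def test_end_to_end_deterministic_given_seed(self):
        cfg = TwoGroupConfig(n_probes=120, frac_deg=0.1, effect_size=2.5, seed=8)
        eset, _ = generate_two_group(cfg)
        deg_cfg = DEGConfig(B=50, seed=9)
        rec1, sum1 = run_two_group_pipeline(eset, deg_cfg)
        rec2, sum2 = run_two_group_pipeline(eset, deg_cfg)
        pd.testing.assert_frame_equal(rec1, rec2)
        assert sum1 == sum2

    def test_null_pvalues_approximately_uniform(self):
        """Marginal empirical p-values under the global null are U(0,1)."""
        cfg = TwoGroupConfig(n_probes=2000, frac_deg=0.0, noise_sd=0.3, seed=12)
        eset, _ = generate_two_group(cfg)
        records, _ = run_two_group_pipeline(eset, DEGConfig(B=200, seed=12))
        for col in ("p_T", "p_lmr"):
            ks = kstest(records[col], "uniform").statistic
            assert ks < 0.05, f"{col}: KS distance {ks:.3f}"

    def test_single_group_rejected(self):
        eset, _ = generate_two_group(TwoGroupConfig(n_probes=30, seed=1))
        eset.samples["group"] = "low"
        with pytest.raises(ValueError, match="2 sample groups"):
            run_two_group_pipeline(ExpressionSet(eset.values, eset.samples))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DEGConfig(alpha=0.0)
        with pytest.raises(ValueError):
            DEGConfig(B=0)
        with pytest.raises(ValueError):
            DEGConfig(fc_cut=-1)
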