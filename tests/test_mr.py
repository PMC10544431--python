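"""Two-sample MR estimators, diagnostics and reporting helpers."""

import numpy as np
import pandas as pd
import pytest

import helpers
from admixmr import (
    cochran_q,
    harmonize,
    ivw,
    mr_egger,
    mr_power_binary,
    or_per_percent,
    quartile_risk_difference,
    radial_outlier_filter,
    weighted_median,
)
from admixmr.mr import InstrumentSet


def make_inst(gamma, big_gamma, se_big_gamma, se_gamma=None):
    gamma = np.asarray(gamma, float)
    return InstrumentSet(
        snp_ids=np.array([f"rs{i}" for i in range(gamma.size)]),
        gamma=gamma,
        se_gamma=np.asarray(se_gamma if se_gamma is not None else np.full_like(gamma, 0.1)),
        big_gamma=np.asarray(big_gamma, float),
        se_big_gamma=np.asarray(se_big_gamma, float),
    )


def _stats(snp, ea, oa, beta, se):
    return pd.DataFrame(
        {
            "snp_id": snp,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": 0.3,
            "beta": beta,
            "se": se,
            "pval": 0.5,
            "n": 100,
        }
    )


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = _stats(["rs1"], ["A"], ["G"], [1.5], [0.2])
        out = _stats(["rs1"], ["A"], ["G"], [-0.05], [0.01])
        inst = harmonize(exp, out)
        assert inst.big_gamma[0] == pytest.approx(-0.05)
        assert inst.n_flipped == 0

    def test_swapped_alleles_flip_outcome(self):
        exp = _stats(["rs1"], ["A"], ["G"], [1.5], [0.2])
        out = _stats(["rs1"], ["G"], ["A"], [-0.05], [0.01])
        inst = harmonize(exp, out)
        assert inst.big_gamma[0] == pytest.approx(0.05)
        assert inst.n_flipped == 1

    def test_incompatible_alleles_dropped(self, caplog):
        exp = _stats(["rs1", "rs2"], ["A", "A"], ["G", "G"], [1.5, 2.0], [0.2, 0.2])
        out = _stats(["rs1", "rs2"], ["A", "A"], ["G", "T"], [-0.05, 0.01], [0.01, 0.01])
        with caplog.at_level("WARNING"):
            inst = harmonize(exp, out)
        assert list(inst.snp_ids) == ["rs1"] and inst.n_dropped == 1

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            harmonize(
                _stats(["rs1"], ["A"], ["G"], [1.0], [0.1]),
                _stats(["rs9"], ["A"], ["G"], [1.0], [0.1]),
            )


class TestIvw:
    # worked example: gamma, Gamma, se_Gamma chosen so the weights are
    # (10000, 40000, 40000) and the ratios (-0.030, -0.025, -0.025)
    EX = make_inst([0.1, 0.2, 0.4], [-0.003, -0.005, -0.010], [0.001, 0.001, 0.002])

    def test_hand_computed_weighted_mean(self):
        np.testing.assert_allclose(self.EX.weights, [10000.0, 40000.0, 40000.0])
        np.testing.assert_allclose(self.EX.ratio, [-0.030, -0.025, -0.025])
        res = ivw(self.EX)
        assert res.beta_hat == pytest.approx(-2300.0 / 90000.0, abs=1e-12)

    def test_equals_zero_intercept_wls_oracle(self, rng):
        gamma = rng.uniform(0.5, 3.0, 25) * rng.choice([-1, 1], 25)
        se_g = rng.uniform(0.05, 0.3, 25)
        big = rng.normal(-0.02 * gamma, 0.01)
        inst = make_inst(gamma, big, rng.uniform(0.005, 0.05, 25), se_g)
        res = ivw(inst)
        slope, se = helpers.ivw_wls_oracle(inst.gamma, inst.big_gamma, inst.se_big_gamma)
        assert res.beta_hat == pytest.approx(slope, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)

    def test_single_iv_is_wald_ratio(self):
        inst = make_inst([0.5], [-0.01], [0.004])
        assert ivw(inst).beta_hat == pytest.approx(-0.02)

    def test_homogeneous_ratios_give_zero_q(self):
        inst = make_inst([0.1, 0.2, 0.4], [-0.002, -0.004, -0.008], [0.001, 0.001, 0.002])
        res = ivw(inst)
        assert res.beta_hat == pytest.approx(-0.02)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-20)
        assert res.q_pval == pytest.approx(1.0)

    def test_ci_brackets_or(self):
        res = ivw(self.EX)
        assert res.ci_low < res.odds_ratio < res.ci_high


class TestCochranQ:
    def test_worked_example(self):
        inst = TestIvw.EX
        q, df, p = cochran_q(inst, ivw(inst).beta_hat)
        assert q == pytest.approx(0.22222, abs=1e-4)
        assert df == 2

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            cochran_q(make_inst([0.5], [0.01], [0.01]), 0.0)

    def test_planted_outlier_exceeds_chi2_tail(self, rng):
        from scipy.stats import chi2

        gamma = np.full(10, 1.0)
        se_G = np.full(10, 0.01)
        big = np.full(10, -0.02)
        big[0] += 10.0 * se_G[0]  # displaced by 10 first-order SDs
        inst = make_inst(gamma, big, se_G)
        q, df, p = cochran_q(inst, ivw(inst).beta_hat)
        assert q > chi2.isf(0.01, df)

    def test_q_equals_sum_of_radial_contributions(self, rng):
        gamma = rng.uniform(0.5, 2.0, 15)
        inst = make_inst(gamma, rng.normal(-0.02 * gamma, 0.01), rng.uniform(0.005, 0.02, 15))
        beta = ivw(inst).beta_hat
        q, *_ = cochran_q(inst, beta)
        q_j = inst.weights * (inst.ratio - beta) ** 2
        assert q == pytest.approx(q_j.sum(), rel=1e-12)


class TestRadial:
    def test_identical_ratios_nothing_removed(self):
        inst = make_inst([0.1, 0.2, 0.4, 0.3], np.array([0.1, 0.2, 0.4, 0.3]) * -0.02,
                         [0.001, 0.001, 0.002, 0.001])
        kept, removed = radial_outlier_filter(inst)
        assert removed.size == 0 and kept.n_iv == 4

    def test_single_displaced_instrument_removed(self, rng):
        gamma = rng.uniform(0.8, 1.2, 21)
        se_G = np.full(21, 0.01)
        big = -0.02 * gamma + rng.normal(0, 0.2 * se_G)
        big[7] += 6.0 * se_G[7]  # one clear outlier
        inst = make_inst(gamma, big, se_G)
        kept, removed = radial_outlier_filter(inst)
        assert list(removed) == ["rs7"]

    def test_alpha_zero_removes_nothing(self, rng):
        gamma = rng.uniform(0.5, 2.0, 10)
        inst = make_inst(gamma, rng.normal(0, 0.05, 10), np.full(10, 0.01))
        kept, removed = radial_outlier_filter(inst, alpha=0.0)
        assert removed.size == 0 and kept.n_iv == 10

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            radial_outlier_filter(make_inst([1.0, 1.0], [0.0, 0.0], [0.01, 0.01]))


class TestEgger:
    def test_recovers_slope_with_null_intercept(self):
        rng = np.random.default_rng(0)
        gamma = rng.uniform(0.5, 3.0, 50)
        se_G = rng.uniform(0.002, 0.01, 50)
        big = -0.025 * gamma + rng.normal(0, 0.2 * se_G)
        res = mr_egger(make_inst(gamma, big, se_G))
        assert res.beta_hat == pytest.approx(-0.025, abs=0.002)
        assert res.egger_intercept_pval > 0.05

    def test_pure_pleiotropy_limit(self):
        gamma = np.array([0.5, 1.0, 1.5, 2.0])
        big = np.full(4, 0.01)  # constant outcome effect, no dose response
        res = mr_egger(make_inst(gamma, big, np.full(4, 0.001)))
        assert res.beta_hat == pytest.approx(0.0, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.01, abs=1e-12)

    def test_too_few_or_degenerate_instruments_error(self):
        with pytest.raises(ValueError):
            mr_egger(make_inst([1.0, 1.2], [0.0, 0.0], [0.01, 0.01]))
        with pytest.raises(ValueError, match="degenerate"):
            mr_egger(make_inst([1.0, 1.0, 1.0], [0.0, 0.01, 0.02], [0.01, 0.01, 0.01]))


class TestWeightedMedian:
    def test_robust_to_single_outlier(self):
        inst = make_inst([1.0, 1.0, 1.0], [1.0, 2.0, 100.0], [1.0, 1.0, 1.0])
        res = weighted_median(inst, n_boot=50, seed=1)
        assert res.beta_hat == pytest.approx(2.0)

    def test_degenerate_all_equal(self):
        inst = make_inst([1.0, 2.0, 4.0], [0.01, 0.02, 0.04], [1e-6, 1e-6, 1e-6])
        res = weighted_median(inst, n_boot=200, seed=2)
        assert res.beta_hat == pytest.approx(0.01)
        assert res.se < 1e-5  # bootstrap SE shrinks with sigma_Gamma

    def test_matches_independent_reimplementation(self, rng):
        gamma = rng.uniform(0.5, 2.5, 30)
        big = rng.normal(-0.02 * gamma, 0.01)
        inst = make_inst(gamma, big, rng.uniform(0.005, 0.02, 30))
        res = weighted_median(inst, n_boot=10, seed=3)
        oracle = helpers.weighted_median_oracle(inst.ratio, inst.weights)
        assert res.beta_hat == pytest.approx(oracle, abs=1e-10)

    def test_bootstrap_seeded(self):
        inst = make_inst([1.0, 1.5, 2.0], [0.01, 0.02, 0.01], [0.01, 0.01, 0.01])
        a = weighted_median(inst, n_boot=100, seed=5)
        b = weighted_median(inst, n_boot=100, seed=5)
        assert a.se == b.se


class TestReorientationInvariance:
    def test_all_estimators_invariant_to_allele_flips(self, rng):
        gamma = rng.uniform(0.5, 2.5, 20)
        big = rng.normal(-0.02 * gamma, 0.005)
        se_G = rng.uniform(0.005, 0.02, 20)
        inst = make_inst(gamma, big, se_G)
        sign = rng.choice([-1.0, 1.0], 20)
        flipped = make_inst(gamma * sign, big * sign, se_G)
        for fn in (
            lambda i: ivw(i).beta_hat,
            lambda i: mr_egger(i).beta_hat,
            lambda i: weighted_median(i, n_boot=10, seed=9).beta_hat,
        ):
            assert fn(inst) == pytest.approx(fn(flipped), abs=1e-12)


class TestReporting:
    def test_or_to_percent_decrease_conversions(self):
        assert or_per_percent(np.log(0.974), 0.001)["percent_decrease"] == pytest.approx(2.6, abs=0.05)
        assert or_per_percent(np.log(0.988), 0.001)["percent_decrease"] == pytest.approx(1.2, abs=0.05)
        assert or_per_percent(0.0, 0.001)["percent_decrease"] == pytest.approx(0.0)

    def test_quartile_risk_difference(self):
        assert quartile_risk_difference(2.6, 36, 49) == pytest.approx(33.8)
        assert quartile_risk_difference(1.2, 54, 79) == pytest.approx(30.0)
        assert quartile_risk_difference(5.0, 40, 40) == 0.0
        with pytest.raises(ValueError):
            quartile_risk_difference(1.0, 50, 40)


class TestPower:
    def test_null_or_gives_alpha(self):
        assert mr_power_binary(5000, 0.5, 0.1, 1.0, alpha=0.05) == pytest.approx(0.05)

    def test_consistency_in_n(self):
        small = mr_power_binary(500, 0.5, 0.1, 0.9)
        large = mr_power_binary(500000, 0.5, 0.1, 0.9)
        assert small < large > 0.999

    def test_protective_and_harmful_symmetric(self):
        assert mr_power_binary(2000, 0.4, 0.1, 0.8) == pytest.approx(
            mr_power_binary(2000, 0.4, 0.1, 1.25)
        )

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            mr_power_binary(1000, 0.5, 1.5, 0.8)
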