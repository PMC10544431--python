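"""Association scans, PheWAS exclusion, explained variance and LD pruning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import helpers
from admixmr import (
    explained_variance,
    greedy_ld_prune,
    instrument_strength,
    ld_r2,
    linear_scan_ancestry,
    logistic_scan_outcome,
    phewas_filter,
)

IDS = lambda m: np.array([f"rs{i:04d}" for i in range(m)])  # noqa: E731


class TestLinearScan:
    def test_perfect_linear_signal(self, rng):
        g = rng.integers(0, 3, size=(50, 1)).astype(float)
        y = 10.0 * g[:, 0]
        out = linear_scan_ancestry(g, y, np.full(50, 50.0), IDS(1))
        assert out.loc[0, "beta"] == pytest.approx(10.0, abs=1e-10)
        assert out.loc[0, "pval"] < 1e-30

    def test_matches_normal_equation_oracle(self, rng):
        n, m = 200, 30
        g = rng.integers(0, 3, size=(n, m)).astype(float)
        age = rng.normal(50, 8, n)
        y = 40 + 0.5 * g[:, 0] + 0.1 * age + rng.normal(0, 5, n)
        out = linear_scan_ancestry(g, y, age, IDS(m))
        for j in [0, 7, 29]:
            X = np.column_stack([np.ones(n), g[:, j], age])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            s2 = resid @ resid / (n - 3)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            assert out.loc[j, "beta"] == pytest.approx(coef[1], abs=1e-8)
            assert out.loc[j, "se"] == pytest.approx(se, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        n = 150
        g = rng.integers(0, 3, size=(n, 1)).astype(float)
        age = rng.normal(50, 8, n)
        y = 30 + 1.2 * g[:, 0] + rng.normal(0, 4, n)
        out = linear_scan_ancestry(g, y, age, IDS(1))
        fit = sm.OLS(y, sm.add_constant(np.column_stack([g[:, 0], age]))).fit()
        assert out.loc[0, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
        assert out.loc[0, "pval"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_null_p_values_uniform(self, rng):
        n, m = 400, 400
        g = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = rng.normal(50, 10, n)  # independent of every SNP
        out = linear_scan_ancestry(g, y, rng.normal(50, 8, n), IDS(m))
        frac = (out["pval"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_monomorphic_dropped(self, rng):
        g = np.column_stack([np.full(30, 1.0), rng.integers(0, 3, 30)]).astype(float)
        out = linear_scan_ancestry(g, rng.normal(size=30), rng.normal(50, 5, 30), IDS(2))
        assert list(out["snp_id"]) == ["rs0001"]


class TestLogisticScan:
    def test_contingency_table_oracle(self):
        # cases: 30 carriers / 70 non-carriers; controls: 50 / 50
        g = np.concatenate([np.ones(30), np.zeros(70), np.ones(50), np.zeros(50)])
        y = np.concatenate([np.ones(100), np.zeros(100)])
        out = logistic_scan_outcome(g[:, None], y, None, IDS(1))
        expected = helpers.logistic_2x2_logor(30, 70, 50, 50)  # ln(3/7)
        assert out.loc[0, "beta"] == pytest.approx(expected, abs=1e-6)

    def test_matches_statsmodels_logit(self, rng):
        n = 300
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        age = rng.normal(50, 8, n)
        lin = -1.0 + 0.4 * g[:, 0] + 0.01 * (age - 50)
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        out = logistic_scan_outcome(g, y, age, IDS(1))
        fit = sm.Logit(y, sm.add_constant(np.column_stack([g[:, 0], age]))).fit(disp=0)
        assert out.loc[0, "beta"] == pytest.approx(fit.params[1], abs=1e-6)
        assert out.loc[0, "se"] == pytest.approx(fit.bse[1], abs=1e-6)

    def test_null_wald_statistics_calibrated(self, rng):
        n, m = 500, 400
        g = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        out = logistic_scan_outcome(g, y, rng.normal(50, 8, n), IDS(m))
        frac_within = (np.abs(out["beta"]) < 3 * out["se"]).mean()
        assert frac_within >= 0.99

    def test_separation_flagged_and_dropped(self, rng, caplog):
        n = 80
        g = np.zeros((n, 2))
        g[:, 1] = rng.binomial(2, 0.5, n)
        y = np.zeros(n)
        y[:40] = 1
        g[:40, 0] = 2.0  # perfect separation on SNP 0
        with caplog.at_level("WARNING"):
            out = logistic_scan_outcome(g, y, rng.normal(50, 8, n), IDS(2))
        assert "rs0000" not in set(out["snp_id"])

    def test_constant_status_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            logistic_scan_outcome(
                rng.binomial(2, 0.5, (20, 1)).astype(float), np.ones(20), None, IDS(1)
            )


class TestPhewasFilter:
    CAT = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "phenotype": ["diabetes", "diabetes", "height"],
            "pval": [1e-9, 1e-7, 1e-20],
        }
    )

    def test_subthreshold_confounder_hit_excluded(self):
        kept = phewas_filter(["rs1", "rs4"], self.CAT)
        assert list(kept) == ["rs4"]

    def test_above_threshold_hit_retained(self):
        assert "rs2" in phewas_filter(["rs2"], self.CAT)

    def test_unlisted_phenotype_ignored(self):
        assert "rs3" in phewas_filter(["rs3"], self.CAT)

    def test_empty_catalog_passthrough(self):
        ids = ["rs1", "rs2"]
        assert list(phewas_filter(ids, None)) == ids
        assert list(phewas_filter(ids, self.CAT.iloc[:0])) == ids

    def test_malformed_row_reports_line(self):
        bad = self.CAT.copy()
        bad.loc[1, "pval"] = -1.0
        with pytest.raises(ValueError, match="line 3"):
            phewas_filter(["rs1"], bad)


class TestExplainedVariance:
    def test_direct_formula_values(self):
        assert explained_variance(0.5, 0.5) == pytest.approx(0.125)
        assert explained_variance(1.0, 0.1) == pytest.approx(0.18)
        # folding: eaf 0.9 has the same MAF as 0.1
        assert explained_variance(1.0, 0.9) == pytest.approx(0.18)

    def test_vanishes_at_maf_boundary(self):
        assert explained_variance(3.0, 1e-9) < 1e-7

    def test_rejects_degenerate_eaf(self):
        with pytest.raises(ValueError):
            explained_variance(1.0, 0.0)


class TestLd:
    def test_identical_and_flipped_vectors(self, rng):
        a = rng.integers(0, 3, 100).astype(float)
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2.0 - a) == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            ld_r2(np.ones(10), np.arange(10.0))

    def test_independent_snps_rarely_exceed_threshold(self, rng):
        g = rng.binomial(2, 0.4, size=(1000, 40)).astype(float)
        r2s = [
            ld_r2(g[:, i], g[:, j]) for i in range(40) for j in range(i + 1, 40)
        ]
        assert np.mean(np.array(r2s) < 0.01) >= 0.95

    def test_duplicate_snp_keeps_highest_explained_variance(self, rng):
        a = rng.binomial(2, 0.5, 200).astype(float)
        g = np.column_stack([a, a])
        kept = greedy_ld_prune(np.array(["rsA", "rsB"]), np.array([0.01, 0.02]), g, 0.01)
        assert list(kept) == ["rsB"]

    def test_independent_candidates_all_retained(self, rng):
        g = rng.binomial(2, 0.5, size=(5000, 8)).astype(float)
        ids = IDS(8)
        kept = greedy_ld_prune(ids, rng.uniform(0, 1, 8), g, 0.01)
        assert set(kept) == set(ids)

    def test_planted_blocks_match_verification_oracle(self, rng):
        n, blocks = 800, 6
        leaders = rng.binomial(2, 0.5, size=(n, blocks)).astype(float)
        cols, ids = [], []
        for b in range(blocks):
            for c in range(3):
                noise = rng.random(n) < 0.02
                col = np.where(noise, rng.binomial(2, 0.5, n), leaders[:, b])
                cols.append(col)
                ids.append(f"rs{b}{c}")
        g = np.column_stack(cols)
        ev = rng.uniform(0.001, 0.05, g.shape[1])
        kept = greedy_ld_prune(np.array(ids), ev, g, 0.01)
        assert helpers.prune_is_valid(kept, ids, ev, g, 0.01)
        assert len(kept) <= blocks + 2


class TestInstrumentStrength:
    def test_single_iv_f_statistic(self):
        rep = instrument_strength(["rs1"], np.array([0.5]), n=102)
        assert rep.f_stat == pytest.approx(100.0)

    def test_zero_contributions(self):
        rep = instrument_strength(IDS(3), np.zeros(3), n=100)
        assert rep.r2_cumulative == 0.0 and rep.f_stat == 0.0

    def test_cumulative_is_sum(self):
        rep = instrument_strength(IDS(3), np.array([0.01, 0.02, 0.04]), n=500)
        assert rep.r2_cumulative == pytest.approx(0.07)

    def test_mis_scaled_betas_rejected(self):
        with pytest.raises(ValueError, match="mis-scaled"):
            instrument_strength(IDS(2), np.array([0.6, 0.6]), n=100)

    def test_mean_per_iv_f_uses_exposure_variance(self):
        # ev on an absolute scale; fractions recovered via the exposure variance
        rep = instrument_strength(["rs1"], np.array([0.0005]), n=714,
                                  exposure_variance=0.01)
        frac = 0.0005 / 0.01
        assert rep.f_mean_per_iv == pytest.approx(712 * frac / (1 - frac))
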