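"""Moderated-t statistics, empirical-Bayes estimation, BH and classification."""

import math
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ce3screen as c
from ce3screen import ConfigurationError, EstimationError, ValidationError, enrichment
from conftest import matrix_from_differences


def closed_form_oracle(diffs, d0, s0_sq):
    """Independent closed-form moderated t, written from the formulas."""
    n = diffs.shape[1]
    fc = diffs.sum(axis=1) / n
    s_sq = ((diffs - fc[:, None]) ** 2).sum(axis=1) / (n - 1)
    s_tilde = (d0 * s0_sq + (n - 1) * s_sq) / (d0 + n - 1)
    t = fc / np.sqrt(s_tilde / n)
    p = 2 * stats.t.sf(np.abs(t), d0 + n - 1)
    return t, p


class TestModeratedT:
    def test_matches_independent_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(0.3, 0.7, (1000, 4))
        m = matrix_from_differences(diffs)
        params = enrichment.ModeratedTestParams(d0=4.0, s0_sq=0.25, d=3)
        rec = c.paired_moderated_t(m, params)
        t_ref, p_ref = closed_form_oracle(diffs, 4.0, 0.25)
        np.testing.assert_allclose(rec["t_mod"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(rec["p"], p_ref, rtol=1e-10)

    def test_identical_arms_give_zero_statistic_and_p_one(self):
        m = matrix_from_differences(np.zeros((5, 4)))
        params = enrichment.ModeratedTestParams(d0=4.0, s0_sq=0.25, d=3)
        rec = c.paired_moderated_t(m, params)
        assert (rec["log2_fc"] == 0).all()
        assert (rec["t_mod"] == 0).all()
        assert (rec["p"] == 1).all()

    def test_d0_zero_recovers_ordinary_paired_t(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0, 1, (50, 4))
        m = matrix_from_differences(diffs)
        rec = c.paired_moderated_t(
            m, enrichment.ModeratedTestParams(d0=0.0, s0_sq=1.0, d=3))
        t_ref = stats.ttest_1samp(diffs, 0, axis=1)
        np.testing.assert_allclose(rec["t_mod"], t_ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(rec["p"], t_ref.pvalue, rtol=1e-10)

    def test_d0_infinite_pins_posterior_variance_at_prior(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0, 1, (50, 4))
        m = matrix_from_differences(diffs)
        rec = c.paired_moderated_t(
            m, enrichment.ModeratedTestParams(d0=math.inf, s0_sq=0.5, d=3))
        assert (rec["s_tilde_sq"] == 0.5).all()
        np.testing.assert_allclose(
            rec["p"], 2 * stats.norm.sf(np.abs(rec["t_mod"])), rtol=1e-12)

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0, 1, (200, 4))
        m = matrix_from_differences(diffs)
        rec = c.paired_moderated_t(
            m, enrichment.ModeratedTestParams(d0=4.0, s0_sq=0.25, d=3))
        lo = np.minimum(rec["s_sq"], 0.25)
        hi = np.maximum(rec["s_sq"], 0.25)
        assert ((rec["s_tilde_sq"] >= lo - 1e-12) & (rec["s_tilde_sq"] <= hi + 1e-12)).all()

    def test_p_monotone_decreasing_in_effect_at_fixed_variance(self):
        params = enrichment.ModeratedTestParams(d0=math.inf, s0_sq=1.0, d=3)
        effects = np.linspace(0.1, 3.0, 10)
        _, t, p = enrichment.moderated_t_from_stats(
            effects, np.ones_like(effects), 4, params)
        assert (np.diff(np.abs(t)) > 0).all()
        assert (np.diff(p) < 0).all()

    def test_matches_limma_ebayes_oracle(self, tmp_path):
        """Cross-check d0, s0^2, t and p against Bioconductor limma."""
        rng = np.random.default_rng(42)
        diffs = rng.normal(0.2, 0.6, (200, 4)) * np.sqrt(
            rng.chisquare(4, 200) / 4)[:, None]
        m = matrix_from_differences(diffs)
        params = c.estimate_eb_params(m)
        rec = c.paired_moderated_t(m, params)
        np.savetxt(tmp_path / "diffs.tsv", diffs, delimiter="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'd <- as.matrix(read.table("{tmp_path}/diffs.tsv", sep="\\t"))\n'
            'fit <- eBayes(lmFit(d, design=matrix(1, ncol(d), 1)))\n'
            'out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],'
            ' d0=fit$df.prior, s0=fit$s2.prior)\n'
            f'write.csv(out, "{tmp_path}/out.csv", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        assert params.d0 == pytest.approx(ref["d0"][0], rel=1e-6)
        assert params.s0_sq == pytest.approx(ref["s0"][0], rel=1e-6)
        np.testing.assert_allclose(rec["t_mod"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(rec["p"], ref["p"], rtol=1e-8)


class TestEbEstimation:
    def test_parameter_recovery_from_scaled_chisquare_variances(self):
        rng = np.random.default_rng(5)
        d0_true, s0_true, d = 4.0, 0.25, 3
        s_sq = s0_true * rng.f(d, d0_true, size=5000)
        d0, s0 = enrichment.fit_f_dist(s_sq, d)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0 == pytest.approx(s0_true, rel=0.10)

    def test_identical_variances_give_infinite_d0_and_common_value(self):
        d0, s0 = enrichment.fit_f_dist(np.full(100, 0.36), d=3)
        assert math.isinf(d0)
        assert s0 == pytest.approx(0.36)

    def test_too_few_proteins_is_estimation_error(self):
        with pytest.raises(EstimationError):
            enrichment.fit_f_dist(np.full(10, 0.5), d=3)

    def test_trigamma_inverse_round_trips(self):
        from scipy.special import polygamma
        for x in (0.05, 0.5, 2.0, 25.0):
            y = float(polygamma(1, x))
            assert enrichment.trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestBhAdjust:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            c.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        assert list(c.bh_adjust([1.0, 1.0])) == [1.0, 1.0]
        assert list(c.bh_adjust([0.2])) == [0.2]

    def test_adjusted_at_least_raw_and_order_invariant(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        adj = c.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(200)
        np.testing.assert_allclose(c.bh_adjust(p[perm]), adj[perm])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(size=100))
        assert (np.diff(c.bh_adjust(p)) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            c.bh_adjust([0.5, 1.2])


class TestClassification:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["protein_id", "log2_fc", "p", "fdr"])

    def test_published_cutoffs(self):
        rec, _ = c.classify_enrichment(self._records([
            ("a", 0.60, 0.04, 0.20),   # beats log2(1.5)=0.585 -> high conf
            ("b", 0.60, 0.04, 0.30),   # fdr above the 0.25 split -> low conf
            ("c", 0.50, 0.01, 0.01),   # below fold cutoff
            ("d", -1.0, 0.001, 0.001),  # depletion is never an interactor call
        ]))
        by_id = rec.set_index("protein_id")["confidence"]
        assert by_id["a"] == "high_confidence"
        assert by_id["b"] == "low_confidence"
        assert by_id["c"] == "not_significant"
        assert by_id["d"] == "not_significant"

    def test_summary_counts_consistent(self):
        rec, summary = c.classify_enrichment(self._records([
            ("a", 0.7, 0.01, 0.1), ("b", -0.7, 0.01, 0.1), ("c", 0.1, 0.5, 0.9),
        ]))
        assert summary["n_significant"] == 1
        assert summary["n_significant_two_sided"] == 2
        assert summary["n_positive_fc"] == 2
        assert (summary["n_high_confidence"] + summary["n_low_confidence"]
                + summary["n_not_significant"]) == 3

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            c.classify_enrichment(self._records([("a", 1, 0.1, 0.1)]), p_threshold=0)


class TestPipelineCalibration:
    def test_null_type_i_rate(self):
        """With no planted effects, ~5% of proteins reach p < 0.05."""
        props = []
        for seed in range(5):
            cfg = c.SimulationConfig(
                seed=300 + seed, n_proteins=2000, planted_binder_fraction=0.0,
                dropout_rate=0.0, endogenous_biotin_fraction=0.0)
            table, _ = c.simulate_ibaq_experiment(cfg)
            rec, _, _ = c.run_enrichment(c.preprocess_chain(table))
            props.append((rec["p"] < 0.05).mean())
        assert np.mean(props) == pytest.approx(0.05, abs=0.01)

    def test_planted_binder_recovery(self):
        """Planted binders at the study conditions are nearly all recovered."""
        sens, fdp = [], []
        for seed in range(5):
            cfg = c.SimulationConfig(
                seed=400 + seed, n_proteins=1000, planted_binder_fraction=0.05,
                planted_log2_effect=2.0, background_log_sd=0.5,
                dropout_rate=0.0, endogenous_biotin_fraction=0.0)
            table, truth = c.simulate_ibaq_experiment(cfg)
            rec, _, _ = c.run_enrichment(c.preprocess_chain(table))
            called = set(rec.loc[rec["confidence"] != "not_significant",
                                 "protein_id"])
            high = set(rec.loc[rec["confidence"] == "high_confidence",
                               "protein_id"])
            sens.append(len(called & truth.binder_ids) / len(truth.binder_ids))
            fdp.append(len(high - truth.binder_ids) / max(len(high), 1))
        assert np.mean(sens) >= 0.90
        assert np.mean(fdp) <= 0.25
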