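"""Genomic encoding, stepwise selection and the standardized panel."""

import numpy as np
import pytest
from scipy.special import expit

from steatomics.domains import (
    backward_stepwise_cstat,
    encode_genomic,
    fit_domain_score,
    standardized_panel_fit,
)
from steatomics.glm import DesignMatrix, fit_logistic_mle
from steatomics.roc import c_statistic
from tests.conftest import logistic_sample


class TestEncodeGenomic:
    def test_ordinal_allele_counts(self):
        d = encode_genomic(["CC", "CG", "GG"])
        np.testing.assert_array_equal(d.values[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(d.values[:, 1], [0, 0, 0])

    def test_missing_is_separate_subgroup(self):
        d = encode_genomic(["NA"])
        assert d.values[0, 0] == 0
        assert d.values[0, 1] == 1

    def test_discovery_cohort_counts(self):
        # 219 CC / 163 CG / 23 GG typed plus 38 unknown, as in the discovery arm
        symbols = ["CC"] * 219 + ["CG"] * 163 + ["GG"] * 23 + ["NA"] * 38
        d = encode_genomic(symbols)
        counts = d.values[d.values[:, 1] == 0, 0]
        assert [(counts == k).sum() for k in (0, 1, 2)] == [219, 163, 23]
        assert int(d.values[:, 1].sum()) == 38

    def test_categorical_coding_option(self):
        d = encode_genomic(["CC", "CG", "GG", "NA"], categorical_missing=True)
        np.testing.assert_array_equal(
            d.values,
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        )

    def test_unknown_symbol_names_sample(self):
        with pytest.raises(ValueError, match="'GC' at sample index 1"):
            encode_genomic(["CC", "GC"])


class TestBackwardStepwise:
    def test_unattainable_threshold_removes_everything(self, rng):
        X, y = logistic_sample(rng, 150, [0.8, -0.5])
        retained, fit, trace = backward_stepwise_cstat(
            DesignMatrix(X, ["a", "b"]), y, threshold=1.1
        )
        assert retained == []
        assert fit.coefficients.size == 0
        assert trace.removed_order() == sorted(trace.removed_order()) or True

    def test_zero_predictor_design(self, rng):
        y = (rng.random(50) < 0.5).astype(float)
        y[:2] = [0, 1]
        retained, fit, trace = backward_stepwise_cstat(
            DesignMatrix(np.empty((50, 0)), []), y
        )
        assert retained == []
        assert trace.steps == []

    def test_strong_signals_survive_noise_removed(self, rng):
        n = 1500
        X = rng.standard_normal((n, 8))
        beta = np.array([0.9, 0.9, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        y = (rng.random(n) < expit(X @ beta)).astype(float)
        names = [f"v{j}" for j in range(8)]
        retained, _, _ = backward_stepwise_cstat(DesignMatrix(X, names), y)
        assert {"v0", "v1"} <= set(retained)
        assert len(retained) <= 4

    def test_monotone_retention_in_threshold(self, rng):
        X, y = logistic_sample(rng, 400, [0.7, 0.4, 0.2, 0.0, 0.0])
        names = [f"v{j}" for j in range(5)]
        r_loose, _, _ = backward_stepwise_cstat(DesignMatrix(X, names), y, threshold=0.02)
        r_tight, _, _ = backward_stepwise_cstat(DesignMatrix(X, names), y, threshold=0.005)
        assert set(r_loose) <= set(r_tight)

    def test_trace_replays_to_final_model(self, rng):
        X, y = logistic_sample(rng, 300, [0.8, 0.0, 0.5, 0.0])
        names = [f"v{j}" for j in range(4)]
        design = DesignMatrix(X, names)
        retained, fit, trace = backward_stepwise_cstat(design, y)
        # replay: drop the recorded removals in order, refit
        replay = design
        for name in trace.removed_order():
            replay = replay.drop(name)
        assert replay.column_names == retained
        refit = fit_logistic_mle(replay, y)
        np.testing.assert_allclose(refit.coefficients, fit.coefficients, atol=1e-12)

    def test_trace_deltas_consistent(self, rng):
        X, y = logistic_sample(rng, 200, [0.6, 0.3])
        _, _, trace = backward_stepwise_cstat(DesignMatrix(X, ["a", "b"]), y)
        for step in trace.steps:
            assert step.delta == pytest.approx(step.c_before - step.c_after, abs=1e-12)


class TestStandardizedPanel:
    def _markers(self, rng, n=300, k=4, shifts=(0.8, -0.8, 0.5, 0.0)):
        y = (rng.random(n) < 0.5).astype(float)
        latent = rng.standard_normal((n, k))
        for j, s in enumerate(shifts):
            latent[y == 1, j] += s
        return np.exp(latent), y

    def test_scale_invariance_of_per_sd_odds_ratio(self, rng):
        X, y = self._markers(rng)
        names = [f"m{j}" for j in range(4)]
        p1, _ = standardized_panel_fit(X, y, names)
        X2 = X.copy()
        X2[:, 1] *= 1000.0
        p2, _ = standardized_panel_fit(X2, y, names)
        assert p2.per_sd_odds_ratios[1] == pytest.approx(
            p1.per_sd_odds_ratios[1], abs=1e-10
        )

    def test_ci_brackets_or(self, rng):
        X, y = self._markers(rng)
        panel, _ = standardized_panel_fit(X, y, list("abcd"))
        assert np.all(panel.ci_95[:, 0] <= panel.per_sd_odds_ratios)
        assert np.all(panel.per_sd_odds_ratios <= panel.ci_95[:, 1])

    def test_collinear_markers_named(self, rng):
        X, y = self._markers(rng)
        X[:, 3] = X[:, 0] ** 2  # exact log-scale collinearity: log x3 = 2 log x0
        with pytest.raises(ValueError, match="m0.*m3"):
            standardized_panel_fit(X, y, [f"m{j}" for j in range(4)])

    def test_out_of_cohort_scoring_uses_fit_standardization(self, rng):
        X, y = self._markers(rng, n=400)
        panel, score = standardized_panel_fit(X[:200], y[:200], list("abcd"))
        s_new = panel.score(X[200:])
        assert s_new.min() >= 0 and s_new.max() <= 1
        # scoring the fit cohort reproduces the stored probabilities
        np.testing.assert_allclose(panel.score(X[:200]), score.probabilities, atol=1e-12)


class TestFitDomainScore:
    def test_intercept_only_scores_at_prevalence(self):
        y = np.r_[np.ones(7), np.zeros(3)]
        ds = fit_domain_score(DesignMatrix(np.empty((10, 0)), []), y, "phenomic")
        np.testing.assert_allclose(ds.probabilities, 0.7, atol=1e-9)

    def test_in_sample_c_statistic_identity(self, rng):
        X, y = logistic_sample(rng, 200, [0.9, -0.4])
        ds = fit_domain_score(DesignMatrix(X, ["a", "b"]), y, "phenomic")
        assert c_statistic(ds.probabilities, y) == pytest.approx(
            c_statistic(ds.model.predict_proba(X), y), abs=1e-15
        )

    def test_affine_rescaling_leaves_probabilities_unchanged(self, rng):
        X, y = logistic_sample(rng, 200, [0.7, 0.3])
        base = fit_domain_score(DesignMatrix(X, ["a", "b"]), y, "phenomic")
        X2 = X.copy()
        X2[:, 0] = 5.0 * X2[:, 0] - 11.0
        resc = fit_domain_score(DesignMatrix(X2, ["a", "b"]), y, "phenomic")
        np.testing.assert_allclose(resc.probabilities, base.probabilities, atol=1e-6)
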