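"""Stacking, the 7-model grid, split verification and cross-validation."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from steatomics.domains import DomainScore, encode_genomic
from steatomics.evaluate import (
    GRID_COMBINATIONS,
    bootstrap_split_verification,
    kfold_cv_auc,
    logistic_fit_score,
    model_grid,
    stack_scores,
    stratified_folds,
    youden_threshold,
)
from steatomics.glm import fit_logistic_mle
from steatomics.roc import c_statistic
from steatomics.simulate import generate_cohort
from tests.conftest import logistic_sample, small_config


def _score(probs, domain, ids=None):
    n = len(probs)
    dummy_y = np.arange(n) % 2.0  # model slot only; stacking ignores it
    fit = fit_logistic_mle(np.asarray(probs, float)[:, None] + np.arange(n)[:, None] * 0.0
                           + np.random.default_rng(0).normal(0, 1e-6, (n, 1)), dummy_y)
    return DomainScore(
        sample_ids=np.asarray(ids if ids is not None else np.arange(len(probs))),
        probabilities=np.asarray(probs, float),
        domain=domain,
        model=fit,
    )


class TestStackScores:
    def test_perfect_predictor_passes_through(self):
        y = np.array([1, 0, 1, 0, 1, 0, 1, 1], float)
        ds = _score(y, "proteomic")
        _, combined = stack_scores([ds], y)
        assert c_statistic(combined.probabilities, y) == 1.0

    def test_nested_loglik_dominance(self, rng):
        X, y = logistic_sample(rng, 200, [1.0, 0.8])
        s1 = _score(expit(X[:, 0]), "phenomic")
        s2 = _score(expit(X[:, 1]), "proteomic")
        both, _ = stack_scores([s1, s2], y)
        one, _ = stack_scores([s1], y)
        other, _ = stack_scores([s2], y)
        assert both.log_likelihood >= one.log_likelihood - 1e-8
        assert both.log_likelihood >= other.log_likelihood - 1e-8

    def test_constant_extra_score_leaves_auc_unchanged(self, rng):
        X, y = logistic_sample(rng, 150, [1.2])
        s1 = _score(expit(X[:, 0]), "proteomic")
        const = _score(np.full(150, 0.5), "genomic")
        const.probabilities = np.full(150, 0.5)
        _, alone = stack_scores([s1], y)
        with pytest.warns(UserWarning, match="constant"):
            _, padded = stack_scores([s1, const], y)
        assert c_statistic(padded.probabilities, y) == pytest.approx(
            c_statistic(alone.probabilities, y), abs=1e-10
        )

    def test_misaligned_samples_reported(self, rng):
        y = np.array([0, 1, 0, 1], float)
        a = _score([0.2, 0.8, 0.3, 0.9], "phenomic", ids=["s1", "s2", "s3", "s4"])
        b = _score([0.2, 0.8, 0.3, 0.9], "proteomic", ids=["s1", "s2", "s3", "s5"])
        with pytest.raises(ValueError, match="misaligned.*s5"):
            stack_scores([a, b], y)


def _grid_inputs(seed, null=False):
    cfg = small_config(seed=seed, n_total=1000, discovery_n=600, genotype_missing_n=40)
    if null:
        cfg = cfg.null_config()
    co = generate_cohort(cfg)
    d, v = co.mask("discovery"), co.mask("validation")
    y_d = co.steatosis_binary[d].astype(float)
    y_v = co.steatosis_binary[v].astype(float)
    gd = encode_genomic(co.genotype_symbols()[d])
    gv = encode_genomic(co.genotype_symbols()[v])
    pfit = fit_logistic_mle(co.phenome[d], y_d)
    ph = (pfit.predict_proba(co.phenome[d]), pfit.predict_proba(co.phenome[v]))
    idx = [s["index"] for s in co.truth["signal_proteins"]]
    prfit = fit_logistic_mle(np.log(co.proteome[d][:, idx]), y_d)
    pr = (
        prfit.predict_proba(np.log(co.proteome[d][:, idx])),
        prfit.predict_proba(np.log(co.proteome[v][:, idx])),
    )
    return gd, gv, ph, pr, y_d, y_v


class TestModelGrid:
    def test_seven_rows_fixed_order_with_cis(self):
        gd, gv, ph, pr, y_d, y_v = _grid_inputs(0)
        rows = model_grid(gd, gv, ph, pr, y_d, y_v, bootstrap_replicates=60, seed=1)
        assert [r.combination for r in rows] == list(GRID_COMBINATIONS)
        for r in rows:
            assert 0 <= r.discovery_auc <= 1 and 0 <= r.validation_auc <= 1
            assert r.discovery_ci[0] <= r.discovery_auc <= r.discovery_ci[1]
            assert r.validation_ci[0] <= r.validation_auc <= r.validation_ci[1]

    def test_duplicated_cohort_gives_equal_aucs(self):
        gd, gv, ph, pr, y_d, y_v = _grid_inputs(1)
        rows = model_grid(gd, gd, (ph[0], ph[0]), (pr[0], pr[0]), y_d, y_d,
                          bootstrap_replicates=60, seed=2)
        for r in rows:
            assert r.discovery_auc == pytest.approx(r.validation_auc, abs=1e-12)

    def test_all_null_generator_chance_level(self):
        aucs = []
        for seed in range(3):
            gd, gv, ph, pr, y_d, y_v = _grid_inputs(seed, null=True)
            rows = model_grid(gd, gv, ph, pr, y_d, y_v, bootstrap_replicates=40, seed=3)
            aucs.extend([r.validation_auc for r in rows])
        assert abs(np.mean(aucs) - 0.5) < 0.06


class TestBootstrapSplitVerification:
    def test_perfectly_separable(self):
        X = np.r_[np.ones((30, 1)), -np.ones((30, 1))] + 0.0
        y = np.r_[np.ones(30), np.zeros(30)]
        bv = bootstrap_split_verification(logistic_fit_score, X, y, replicates=40, seed=0)
        assert bv.ci_sensitivity == (1.0, 1.0)
        assert bv.ci_specificity == (1.0, 1.0)

    def test_seed_determinism(self, rng):
        X, y = logistic_sample(rng, 120, [1.0])
        a = bootstrap_split_verification(logistic_fit_score, X, y, replicates=50, seed=9)
        b = bootstrap_split_verification(logistic_fit_score, X, y, replicates=50, seed=9)
        np.testing.assert_array_equal(a.sensitivities, b.sensitivities)
        np.testing.assert_array_equal(a.specificities, b.specificities)

    def test_binormal_youden_point_recovered(self, rng):
        # equal-variance binormal with delta = 1.5: optimum sens = spec = Phi(0.75).
        # n is large so the empirical score distribution (the resampling
        # population) is close to the binormal law the closed form assumes.
        n = 2400
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        x = np.r_[rng.normal(1.5, 1, n // 2), rng.normal(0, 1, n // 2)][:, None]
        bv = bootstrap_split_verification(
            logistic_fit_score, x, y, replicates=150, seed=4
        )
        target = norm.cdf(0.75)
        assert abs(bv.sensitivities.mean() + bv.specificities.mean() - 2 * target) < 0.05

    def test_youden_threshold_on_known_scores(self):
        scores = np.array([0.1, 0.2, 0.6, 0.7, 0.8])
        labels = np.array([0, 0, 1, 1, 1])
        thr = youden_threshold(scores, labels)
        assert 0.2 < thr <= 0.6


class TestKFoldCV:
    def test_partition_property(self, rng):
        y = (rng.random(103) < 0.6).astype(float)
        folds = stratified_folds(y, 10, seed=0)
        sizes = [f.size for f in folds]
        assert max(sizes) - min(sizes) <= 1
        allidx = np.concatenate(folds)
        assert len(allidx) == 103 and len(np.unique(allidx)) == 103

    def test_leave_one_out_fold_sizes(self, rng):
        y = np.r_[np.ones(6), np.zeros(6)]
        folds = stratified_folds(y, 12, seed=1)
        assert all(f.size == 1 for f in folds)

    def test_null_cv_auc_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((1000, 5))
            y = (rng.random(1000) < 0.6).astype(float)
            auc, _ = kfold_cv_auc(logistic_fit_score, X, y, k=10, seed=seed)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03
        assert max(abs(a - 0.5) for a in aucs) < 0.08

    def test_stratification_keeps_both_classes(self, rng):
        y = np.r_[np.ones(12), np.zeros(88)]
        folds = stratified_folds(y, 10, seed=3)
        for f in folds:
            assert y[f].max() == 1 and y[f].min() == 0
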