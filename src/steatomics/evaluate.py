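"""Multi-component (late-fusion) modelling and evaluation.

The three single-domain classifier scores are combined by a second-level
logistic regression ("stacking"); the seven-combination AUC grid reports
in-sample discovery performance and frozen-model validation performance with
percentile-bootstrap confidence intervals, alongside the 2500-replicate
80/20 split verification (sensitivity/specificity at the training Youden
threshold) and stratified 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .glm import DesignMatrix, fit_logistic_mle
from .roc import bootstrap_auc_ci, c_statistic

__all__ = [
    "ModelGridRow",
    "BootstrapVerification",
    "stack_scores",
    "model_grid",
    "bootstrap_split_verification",
    "kfold_cv_auc",
    "stratified_folds",
    "youden_threshold",
    "GRID_COMBINATIONS",
]

# Fixed row order of the 7-model grid: genotype alone, each domain alone,
# then the pairwise and three-domain stacks.
GRID_COMBINATIONS = ("G", "P", "Pr", "P+G", "Pr+G", "Pr+P", "Pr+P+G")

FitScore = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
"""Model specification: (X_train, y_train, X_eval) -> scores on X_eval."""


@dataclass
class ModelGridRow:
    combination: str
    discovery_auc: float
    discovery_ci: tuple[float, float]
    validation_auc: float
    validation_ci: tuple[float, float]


@dataclass
class BootstrapVerification:
    replicates: int
    train_fraction: float
    sensitivities: np.ndarray
    specificities: np.ndarray
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]
    threshold_rule: str
    seed: int | None
    redrawn: int = 0


def _align(domain_scores: Sequence, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if not domain_scores:
        raise ValueError("at least one domain score is required")
    ref_ids = np.asarray(domain_scores[0].sample_ids)
    for ds in domain_scores[1:]:
        ids = np.asarray(ds.sample_ids)
        if ids.shape != ref_ids.shape or np.any(ids != ref_ids):
            only_ref = set(map(str, ref_ids)) - set(map(str, ids))
            only_other = set(map(str, ids)) - set(map(str, ref_ids))
            raise ValueError(
                "misaligned sample sets between domain scores; "
                f"only in first: {sorted(only_ref)[:5]}, "
                f"only in {ds.domain}: {sorted(only_other)[:5]}"
            )
    X = np.column_stack([ds.probabilities for ds in domain_scores])
    names = [f"score_{ds.domain}" for ds in domain_scores]
    y = np.asarray(labels, dtype=float).ravel()
    if y.size != ref_ids.size:
        raise ValueError("labels and scores have different lengths")
    return X, y, names


def stack_scores(domain_scores: Sequence, labels):
    """Second-level logistic regression on 1–3 domain probability scores.

    Returns the fitted stacker and the combined ``DomainScore`` (predicted
    probability of steatosis).  Inputs must share an identical sample_id
    vector; any discrepancy is reported explicitly.
    """
    from .domains import DomainScore

    X, y, names = _align(domain_scores, labels)
    keep = X.std(axis=0) > 1e-12
    if not keep.all():
        import warnings

        dropped = [nm for nm, k in zip(names, keep) if not k]
        warnings.warn(
            "constant score columns carry no information and are dropped: "
            + ", ".join(dropped),
            stacklevel=2,
        )
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
    fit = fit_logistic_mle(X, y, column_names=names)
    combined = DomainScore(
        sample_ids=np.asarray(domain_scores[0].sample_ids),
        probabilities=fit.predict_proba(X),
        domain="+".join(ds.domain for ds in domain_scores),
        model=fit,
    )
    return fit, combined


def model_grid(
    genomic_design_disc: DesignMatrix,
    genomic_design_val: DesignMatrix,
    pheno_scores: tuple[np.ndarray, np.ndarray],
    prot_scores: tuple[np.ndarray, np.ndarray],
    labels_disc: np.ndarray,
    labels_val: np.ndarray,
    bootstrap_replicates: int = 2000,
    seed: int | None = None,
) -> list[ModelGridRow]:
    """The seven-combination AUC grid (discovery in-sample, frozen validation).

    ``pheno_scores`` / ``prot_scores`` are (discovery, validation) probability
    vectors produced by discovery-fitted domain models.  Each combination is
    fitted on the discovery cohort; validation samples are scored with the
    frozen discovery model.  Percentile-bootstrap CIs resample (score, label)
    pairs within each cohort.
    """
    y_d = np.asarray(labels_disc, dtype=float).ravel()
    y_v = np.asarray(labels_val, dtype=float).ravel()
    ph_d, ph_v = (np.asarray(v, float) for v in pheno_scores)
    pr_d, pr_v = (np.asarray(v, float) for v in prot_scores)

    # genomic probability score for stacking: genotype-only model on discovery
    gfit = fit_logistic_mle(genomic_design_disc, y_d)
    g_d = gfit.predict_proba(genomic_design_disc.values)
    g_v = gfit.predict_proba(genomic_design_val.values)

    parts_d = {"G": g_d, "P": ph_d, "Pr": pr_d}
    parts_v = {"G": g_v, "P": ph_v, "Pr": pr_v}

    rng = np.random.default_rng(seed)
    rows: list[ModelGridRow] = []
    for combo in GRID_COMBINATIONS:
        if combo == "G":
            Xd, names = genomic_design_disc.values, genomic_design_disc.column_names
            Xv = genomic_design_val.values
        else:
            keys = combo.split("+")
            Xd = np.column_stack([parts_d[k] for k in keys])
            Xv = np.column_stack([parts_v[k] for k in keys])
            names = [f"score_{k}" for k in keys]
        fit = fit_logistic_mle(Xd, y_d, column_names=list(names))
        s_d = fit.predict_proba(Xd)
        s_v = fit.predict_proba(Xv)
        auc_d = c_statistic(s_d, y_d)
        auc_v = c_statistic(s_v, y_v)
        ci_d = bootstrap_auc_ci(
            s_d, y_d, replicates=bootstrap_replicates, seed=int(rng.integers(2**31))
        )
        ci_v = bootstrap_auc_ci(
            s_v, y_v, replicates=bootstrap_replicates, seed=int(rng.integers(2**31))
        )
        rows.append(ModelGridRow(combo, auc_d, ci_d, auc_v, ci_v))
    return rows


def grid_to_frame(rows: list[ModelGridRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.combination for r in rows],
            "discovery_auc": [r.discovery_auc for r in rows],
            "discovery_ci_low": [r.discovery_ci[0] for r in rows],
            "discovery_ci_high": [r.discovery_ci[1] for r in rows],
            "validation_auc": [r.validation_auc for r in rows],
            "validation_ci_low": [r.validation_ci[0] for r in rows],
            "validation_ci_high": [r.validation_ci[1] for r in rows],
        }
    )


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability threshold maximizing sensitivity + specificity − 1.

    Computed over the unique observed scores; a sample is called positive
    when its score is >= the threshold.  Ties in J break toward the higher
    threshold (more specific operating point).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    uniq = np.unique(s)
    best_thr, best_j = uniq[-1], -np.inf
    n1 = (y == 1).sum()
    n0 = y.size - n1
    for thr in uniq[::-1]:
        pred = s >= thr
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_thr = j, thr
    return float(best_thr)


def _stratified_split(rng, y, train_fraction):
    tr = []
    te = []
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        k = int(round(train_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        tr.append(idx[:k])
        te.append(idx[k:])
    return np.concatenate(tr), np.concatenate(te)


def logistic_fit_score(X_tr, y_tr, X_ev) -> np.ndarray:
    """Default model specification: plain logistic regression."""
    fit = fit_logistic_mle(X_tr, y_tr)
    return fit.predict_proba(X_ev)


def bootstrap_split_verification(
    fit_score: FitScore,
    X: np.ndarray,
    y: np.ndarray,
    replicates: int = 2500,
    train_fraction: float = 0.8,
    seed: int | None = None,
    threshold_rule: str = "youden",
    fixed_threshold: float = 0.5,
) -> BootstrapVerification:
    """Repeated stratified 80/20 split verification of a model specification.

    Per replicate: refit on the training split, choose the operating
    threshold on the training scores (Youden's J by default; "fixed" uses
    ``fixed_threshold``), then record sensitivity and specificity on the test
    split.  95% percentile intervals summarize the replicate distributions.
    Degenerate single-class test splits are redrawn and counted.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sens = np.empty(replicates)
    spec = np.empty(replicates)
    redrawn = 0
    for b in range(replicates):
        for _attempt in range(100):
            tr, te = _stratified_split(rng, y, train_fraction)
            if y[te].min() == 0 and y[te].max() == 1:
                break
            redrawn += 1
        else:
            raise RuntimeError("could not draw a two-class test split")
        s_tr = fit_score(X[tr], y[tr], X[tr])
        s_te = fit_score(X[tr], y[tr], X[te])
        if threshold_rule == "youden":
            thr = youden_threshold(s_tr, y[tr])
        elif threshold_rule == "fixed":
            thr = fixed_threshold
        else:
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        pred = s_te >= thr
        yt = y[te]
        sens[b] = (pred & (yt == 1)).sum() / (yt == 1).sum()
        spec[b] = (~pred & (yt == 0)).sum() / (yt == 0).sum()
    return BootstrapVerification(
        replicates=replicates,
        train_fraction=train_fraction,
        sensitivities=sens,
        specificities=spec,
        ci_sensitivity=tuple(np.quantile(sens, [0.025, 0.975])),
        ci_specificity=tuple(np.quantile(spec, [0.025, 0.975])),
        threshold_rule=threshold_rule,
        seed=seed,
        redrawn=redrawn,
    )


def stratified_folds(y: np.ndarray, k: int, seed: int | None = None) -> list[np.ndarray]:
    """Disjoint stratified folds whose sizes differ by at most one."""
    y = np.asarray(y).ravel()
    if k > y.size:
        raise ValueError(f"k={k} exceeds n={y.size}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in np.unique(y):
        idx = rng.permutation(np.nonzero(y == cls)[0])
        for i, j in enumerate(idx):
            folds[(start + i) % k].append(int(j))
        start += idx.size
    return [np.array(sorted(f), dtype=int) for f in folds]


def kfold_cv_auc(
    fit_score: FitScore,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Stratified k-fold cross-validated AUC.

    Out-of-fold scores are pooled into a single AUC; per-fold AUCs are
    returned alongside (NaN for folds too small to contain both classes is
    not allowed — such folds raise with a suggestion to lower ``k``).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    folds = stratified_folds(y, k, seed)
    pooled = np.empty(y.size)
    per_fold = np.empty(len(folds))
    for i, te in enumerate(folds):
        tr = np.setdiff1d(np.arange(y.size), te)
        if y[tr].min() == y[tr].max():
            raise ValueError(f"training portion of fold {i} has one class; use smaller k")
        pooled[te] = fit_score(X[tr], y[tr], X[te])
        if te.size and y[te].min() == 0 and y[te].max() == 1:
            per_fold[i] = c_statistic(pooled[te], y[te])
        elif k == y.size:
            per_fold[i] = np.nan  # leave-one-out folds cannot have both classes
        else:
            raise ValueError(f"fold {i} contains a single class; use smaller k")
    return c_statistic(pooled, y), per_fold
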