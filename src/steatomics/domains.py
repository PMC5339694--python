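"""The three single-domain steatosis classifiers.

* genomic — PNPLA3-style risk-allele count as an ordinal covariate plus a
  missing-genotype indicator (the "separate subgroup" coding);
* phenomic — backwards stepwise logistic model over the clinical variables,
  removing variables whose in-sample c-statistic decrement is below 0.01;
* proteomic — a standardized (per-SD) logistic panel over the
  stability-selected markers.

Each classifier emits a ``DomainScore``: the per-sample predicted probability
of steatosis, which is the unit the multi-component stacker consumes.
Validation-cohort scores always reuse discovery-fitted coefficients and
standardization parameters (a refit variant is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import DesignMatrix, FittedLogit, fit_logistic_mle
from .roc import c_statistic

__all__ = [
    "DomainScore",
    "StepwiseTrace",
    "PanelModel",
    "encode_genomic",
    "backward_stepwise_cstat",
    "standardized_panel_fit",
    "fit_domain_score",
]

_GENO_ALPHABET = {"CC": 0, "CG": 1, "GG": 2}


@dataclass
class DomainScore:
    """Per-sample predicted probability of steatosis from one domain."""

    sample_ids: np.ndarray
    probabilities: np.ndarray
    domain: str  # genomic / phenomic / proteomic / combined
    model: FittedLogit
    fit_cohort: str = "discovery"

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ValueError("probabilities outside [0, 1]")
        if len(self.sample_ids) != self.probabilities.size:
            raise ValueError("one probability per sample required")


@dataclass
class StepwiseStep:
    candidate: str
    c_before: float
    c_after: float
    delta: float
    removed: bool


@dataclass
class StepwiseTrace:
    """Audit log of every candidate evaluation of the stepwise search."""

    steps: list[StepwiseStep]

    def removed_order(self) -> list[str]:
        return [s.candidate for s in self.steps if s.removed]


@dataclass
class PanelModel:
    """A standardized logistic marker panel with per-SD odds ratios."""

    marker_names: list[str]
    center: np.ndarray  # fit-cohort log-scale means
    scale: np.ndarray  # fit-cohort log-scale SDs
    fit: FittedLogit
    per_sd_odds_ratios: np.ndarray
    ci_95: np.ndarray  # (k, 2)
    p_values: np.ndarray

    def score(self, raw_markers: np.ndarray) -> np.ndarray:
        """Score new samples (raw positive marker columns, fit-cohort scaling)."""
        X = np.asarray(raw_markers, dtype=float)
        if np.any(X <= 0):
            raise ValueError("marker abundances must be positive")
        Z = (np.log(X) - self.center) / self.scale
        return self.fit.predict_proba(Z)


def encode_genomic(
    genotypes, categorical_missing: bool = False
) -> DesignMatrix:
    """Encode CC/CG/GG/NA genotype symbols as a design matrix.

    Default coding: one ordinal column counting risk alleles (CC→0, CG→1,
    GG→2; missing→0) plus a 0/1 missing indicator — missing genotypes form
    their own subgroup.  ``categorical_missing=True`` switches to a 4-level
    dummy coding (CG, GG, missing vs CC reference).
    """
    counts = []
    missing = []
    for i, g in enumerate(genotypes):
        sym = str(g).strip().upper()
        if sym in ("NA", "NAN", "", "-1"):
            counts.append(0)
            missing.append(1)
        elif sym in _GENO_ALPHABET:
            counts.append(_GENO_ALPHABET[sym])
            missing.append(0)
        else:
            raise ValueError(f"unknown genotype symbol {g!r} at sample index {i}")
    counts = np.array(counts, dtype=float)
    missing = np.array(missing, dtype=float)
    if categorical_missing:
        cols = np.column_stack(
            [
                (counts == 1) & (missing == 0),
                (counts == 2) & (missing == 0),
                missing,
            ]
        ).astype(float)
        return DesignMatrix(cols, ["geno_CG", "geno_GG", "geno_missing"])
    return DesignMatrix(
        np.column_stack([counts, missing]), ["risk_alleles", "geno_missing"]
    )


def _insample_c(design: DesignMatrix, y: np.ndarray) -> tuple[float, FittedLogit]:
    if design.p == 0:
        fit = fit_logistic_mle(np.empty((y.size, 0)), y)
        return 0.5, fit
    fit = fit_logistic_mle(design, y)
    return c_statistic(fit.predict_proba(design.values), y), fit


def backward_stepwise_cstat(
    design: DesignMatrix,
    labels,
    threshold: float = 0.01,
) -> tuple[list[str], FittedLogit, StepwiseTrace]:
    """Backwards stepwise variable selection by in-sample c-statistic decrement.

    Starting from the full model, each round refits the model with each
    remaining variable removed in turn and computes the c-statistic decrement
    its removal causes; the variable with the smallest decrement is dropped
    if that decrement is below ``threshold`` (ties break lexicographically),
    and the search stops once every candidate costs at least ``threshold``.
    Every evaluation is recorded in the trace.
    """
    y = np.asarray(labels, dtype=float).ravel()
    current = design
    steps: list[StepwiseStep] = []
    c_full, fit = _insample_c(current, y)
    while current.p > 0:
        evals = []
        for name in current.column_names:
            reduced = current.drop(name)
            c_red, fit_red = _insample_c(reduced, y)
            evals.append((name, c_red, fit_red))
        # smallest decrement first, lexicographic tie-break
        evals.sort(key=lambda e: (c_full - e[1], e[0]))
        best_name, best_c, best_fit = evals[0]
        best_delta = c_full - best_c
        qualifies = best_delta < threshold
        for name, c_red, _f in evals:
            steps.append(
                StepwiseStep(
                    candidate=name,
                    c_before=c_full,
                    c_after=c_red,
                    delta=c_full - c_red,
                    removed=qualifies and name == best_name,
                )
            )
        if not qualifies:
            break
        current = current.drop(best_name)
        c_full, fit = best_c, best_fit
    return list(current.column_names), fit, StepwiseTrace(steps)


def standardized_panel_fit(
    raw_markers: np.ndarray,
    labels,
    marker_names: list[str],
    sample_ids=None,
    domain: str = "proteomic",
) -> tuple[PanelModel, DomainScore]:
    """Fit the multivariate logistic panel on log-standardized markers.

    Markers are log-transformed and rescaled to mean 0 / SD 1 on the fit
    cohort before entering the model, so ``exp(coefficient)`` is the odds of
    steatosis per 1-SD increase in (log) marker level.  Wald 95% CIs and
    p-values accompany each odds ratio.  Collinear marker pairs raise with
    their names.
    """
    X = np.asarray(raw_markers, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if np.any(X <= 0):
        raise ValueError("marker abundances must be positive")
    L = np.log(X)
    center = L.mean(axis=0)
    scale = L.std(axis=0)
    if np.any(scale < 1e-12):
        bad = [marker_names[j] for j in np.nonzero(scale < 1e-12)[0]]
        raise ValueError("constant marker columns: " + ", ".join(bad))
    Z = (L - center) / scale
    corr = np.corrcoef(Z, rowvar=False)
    if Z.shape[1] > 1:
        iu = np.triu_indices(Z.shape[1], k=1)
        dup = np.nonzero(np.abs(corr[iu]) > 1 - 1e-10)[0]
        if dup.size:
            i, j = iu[0][dup[0]], iu[1][dup[0]]
            raise ValueError(
                f"collinear markers: {marker_names[i]} and {marker_names[j]}"
            )
    fit = fit_logistic_mle(Z, y, column_names=list(marker_names))
    if fit.standard_errors is None:
        se = np.full(Z.shape[1], np.nan)
    else:
        se = fit.standard_errors
    z975 = stats.norm.ppf(0.975)
    ors = np.exp(fit.coefficients)
    ci = np.column_stack(
        [np.exp(fit.coefficients - z975 * se), np.exp(fit.coefficients + z975 * se)]
    )
    pv = 2.0 * stats.norm.sf(np.abs(fit.coefficients / se))
    panel = PanelModel(
        marker_names=list(marker_names),
        center=center,
        scale=scale,
        fit=fit,
        per_sd_odds_ratios=ors,
        ci_95=ci,
        p_values=pv,
    )
    ids = sample_ids if sample_ids is not None else np.arange(y.size)
    score = DomainScore(
        sample_ids=np.asarray(ids),
        probabilities=fit.predict_proba(Z),
        domain=domain,
        model=fit,
    )
    return panel, score


def fit_domain_score(
    design: DesignMatrix,
    labels,
    domain: str,
    sample_ids=None,
) -> DomainScore:
    """Fit a logistic model on a domain design and score the fit cohort.

    New cohorts are scored with the frozen fitted model via
    ``score.model.predict_proba`` — no refitting.
    """
    y = np.asarray(labels, dtype=float).ravel()
    fit = fit_logistic_mle(design, y)
    probs = fit.predict_proba(design.values) if design.p else np.full(y.size, y.mean())
    ids = sample_ids if sample_ids is not None else np.arange(y.size)
    return DomainScore(
        sample_ids=np.asarray(ids), probabilities=probs, domain=domain, model=fit
    )
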