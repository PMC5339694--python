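"""High-level workflows shared by the pipeline driver, tests and acceptance.

``fit_domains`` trains all three single-domain classifiers on the discovery
cohort of a (synthetic or loaded) cohort and scores both cohorts with the
frozen discovery models; ``holdout_aucs`` reduces that to the
validation-cohort AUC of each domain and of the three-domain stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import backward_stepwise_cstat, encode_genomic, standardized_panel_fit
from .evaluate import GRID_COMBINATIONS
from .glm import DesignMatrix, FittedLogit, fit_logistic_mle
from .lasso import make_lambda_grid
from .roc import c_statistic
from .simulate import SyntheticCohort
from .stability import (
    bonferroni_screen,
    log_standardize,
    select_stable_markers,
    stability_paths,
)

__all__ = ["DomainFits", "fit_domains", "holdout_aucs"]


@dataclass
class DomainFits:
    """Discovery-fitted domain models and their scores on both cohorts."""

    genomic_design_disc: DesignMatrix
    genomic_design_val: DesignMatrix
    genomic_fit: FittedLogit
    geno_disc: np.ndarray
    geno_val: np.ndarray
    pheno_retained: list[str]
    pheno_fit: FittedLogit
    pheno_trace: object
    pheno_disc: np.ndarray
    pheno_val: np.ndarray
    panel: object
    panel_markers: list[str]
    prot_disc: np.ndarray
    prot_val: np.ndarray
    profile: object
    screen: object
    y_disc: np.ndarray
    y_val: np.ndarray
    ids_disc: np.ndarray
    ids_val: np.ndarray


def fit_domains(
    cohort: SyntheticCohort,
    stability_B: int = 100,
    panel_k: int = 8,
    lambda_points: int = 30,
    lambda_min_ratio: float = 0.01,
    stepwise_threshold: float = 0.01,
    seed: int | None = None,
    bonferroni_prefilter: bool = False,
    run_screen: bool = True,
) -> DomainFits:
    """Train genomic, phenomic and proteomic classifiers on discovery.

    Validation scores always come from the frozen discovery models (and the
    discovery standardization parameters for the proteomic panel).
    """
    disc = cohort.mask("discovery")
    val = cohort.mask("validation")
    y_d = cohort.steatosis_binary[disc].astype(float)
    y_v = cohort.steatosis_binary[val].astype(float)

    # genomic
    gd = encode_genomic(cohort.genotype_symbols()[disc])
    gv = encode_genomic(cohort.genotype_symbols()[val])
    gfit = fit_logistic_mle(gd, y_d)
    geno_d = gfit.predict_proba(gd.values)
    geno_v = gfit.predict_proba(gv.values)

    # phenomic
    pdes = DesignMatrix(cohort.phenome[disc], cohort.pheno_names)
    retained, pfit, trace = backward_stepwise_cstat(
        pdes, y_d, threshold=stepwise_threshold
    )
    keep = [cohort.pheno_names.index(nm) for nm in retained]
    if retained:
        ph_d = pfit.predict_proba(cohort.phenome[disc][:, keep])
        ph_v = pfit.predict_proba(cohort.phenome[val][:, keep])
    else:
        ph_d = np.full(int(disc.sum()), y_d.mean())
        ph_v = np.full(int(val.sum()), y_d.mean())

    # proteomic
    screen = (
        bonferroni_screen(cohort.proteome[disc], y_d, feature_names=cohort.protein_names)
        if (run_screen or bonferroni_prefilter)
        else None
    )
    Z_d = log_standardize(cohort.proteome[disc])
    grid = make_lambda_grid(Z_d, y_d, n_points=lambda_points, min_ratio=lambda_min_ratio)
    profile = stability_paths(
        Z_d,
        y_d,
        B=stability_B,
        lambda_grid=grid,
        seed=seed,
        feature_names=cohort.protein_names,
        already_standardized=True,
        prefilter_names=screen.significant if bonferroni_prefilter else None,
    )
    markers = select_stable_markers(profile, k=panel_k)
    midx = [cohort.protein_names.index(m) for m in markers.selected]
    panel, prot_score_d = standardized_panel_fit(
        cohort.proteome[disc][:, midx],
        y_d,
        markers.selected,
        sample_ids=cohort.sample_id[disc],
    )
    prot_d = prot_score_d.probabilities
    prot_v = panel.score(cohort.proteome[val][:, midx])

    return DomainFits(
        genomic_design_disc=gd,
        genomic_design_val=gv,
        genomic_fit=gfit,
        geno_disc=geno_d,
        geno_val=geno_v,
        pheno_retained=retained,
        pheno_fit=pfit,
        pheno_trace=trace,
        pheno_disc=ph_d,
        pheno_val=ph_v,
        panel=panel,
        panel_markers=markers.selected,
        prot_disc=prot_d,
        prot_val=prot_v,
        profile=profile,
        screen=screen,
        y_disc=y_d,
        y_val=y_v,
        ids_disc=cohort.sample_id[disc],
        ids_val=cohort.sample_id[val],
    )


def holdout_aucs(fits: DomainFits) -> dict[str, float]:
    """Validation-cohort AUC per domain and for the three-domain stack."""
    out = {
        "genomic": c_statistic(fits.geno_val, fits.y_val),
        "phenomic": c_statistic(fits.pheno_val, fits.y_val),
        "proteomic": c_statistic(fits.prot_val, fits.y_val),
    }
    Xd = np.column_stack([fits.prot_disc, fits.pheno_disc, fits.geno_disc])
    Xv = np.column_stack([fits.prot_val, fits.pheno_val, fits.geno_val])
    stack = fit_logistic_mle(Xd, fits.y_disc, column_names=["Pr", "P", "G"])
    out["stack"] = c_statistic(stack.predict_proba(Xv), fits.y_val)
    return out
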