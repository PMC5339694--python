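"""End-to-end pipeline orchestration.

Runs, in order: simulate (optional) → cohort characterization (table one) →
genomic / phenomic / proteomic domain classifiers (Bonferroni screen,
stability selection, standardized panel) → late-fusion stacking → the
7-model AUC grid, 80/20 bootstrap verification and 10-fold CV.  Every stage
is seeded from the single pipeline seed, so a fixed seed reproduces the
results directory byte-for-byte.

Outputs written to the results directory: table1.csv, stability_profile.csv,
panel.csv, scores.csv, model_grid.csv, bootstrap.csv, cv.csv, log.txt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .evaluate import (
    bootstrap_split_verification,
    grid_to_frame,
    kfold_cv_auc,
    logistic_fit_score,
    model_grid,
)
from .simulate import generate_cohort
from .tableone import characterize_cohort
from .workflows import fit_domains

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

MANIFEST = [
    "table1.csv",
    "stability_profile.csv",
    "panel.csv",
    "scores.csv",
    "model_grid.csv",
    "bootstrap.csv",
    "cv.csv",
    "log.txt",
]


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the flat config-file keys."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stability_B: int = 100
    panel_k: int = 8
    lambda_points: int = 30
    lambda_min_ratio: float = 0.01
    bonferroni_prefilter: bool = False
    stepwise_threshold: float = 0.01
    bootstrap_replicates: int = 2500
    grid_bootstrap_replicates: int = 2000
    train_fraction: float = 0.8
    threshold_rule: str = "youden"
    cv_folds: int = 10
    seed: int = 0
    out_dir: Path = Path("results")

    def validate(self) -> None:
        if self.stability_B < 2:
            raise ValueError("stability_B must be >= 2")
        if self.panel_k < 1:
            raise ValueError("panel_k must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.bootstrap_replicates < 20 or self.grid_bootstrap_replicates < 20:
            raise ValueError("bootstrap replicate counts must be >= 20")


@dataclass
class PipelineResult:
    out_dir: Path
    grid: pd.DataFrame
    retained_pheno: list[str]
    panel_markers: list[str]
    n_bonferroni: int


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a freshly simulated cohort."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    rng = np.random.default_rng(config.seed)

    def stage_seed(name: str) -> int:
        s = int(rng.integers(2**31))
        log.append(f"seed[{name}] = {s}")
        return s

    sim = config.simulation
    cohort = generate_cohort(sim)
    log.append(f"simulate: n={cohort.n} seed={sim.seed}")
    disc = cohort.mask("discovery")
    val = cohort.mask("validation")
    y_d = cohort.steatosis_binary[disc].astype(float)
    y_v = cohort.steatosis_binary[val].astype(float)

    # --- table one -------------------------------------------------------
    frame = pd.DataFrame(cohort.phenome, columns=cohort.pheno_names)
    frame["cohort"] = cohort.cohort
    frame["steatosis_grade"] = cohort.steatosis_grade.astype(str)
    frame["genotype"] = cohort.genotype_symbols()
    n_bin = sim.n_pheno_binary
    types = {
        name: ("categorical" if j >= sim.n_pheno - n_bin else "continuous")
        for j, name in enumerate(cohort.pheno_names)
    }
    types["steatosis_grade"] = "categorical"
    types["genotype"] = "categorical"
    table1 = characterize_cohort(frame, types)
    table1.to_csv(out / "table1.csv", index=False, float_format="%.12g")
    log.append(f"table1: {len(table1)} rows")

    # --- domain classifiers ---------------------------------------------
    fits = fit_domains(
        cohort,
        stability_B=config.stability_B,
        panel_k=config.panel_k,
        lambda_points=config.lambda_points,
        lambda_min_ratio=config.lambda_min_ratio,
        stepwise_threshold=config.stepwise_threshold,
        seed=stage_seed("stability"),
        bonferroni_prefilter=config.bonferroni_prefilter,
    )
    screen, profile, panel = fits.screen, fits.profile, fits.panel
    log.append(
        f"bonferroni: threshold={screen.threshold:.3e} "
        f"significant={len(screen.significant)}"
    )
    prof_df = pd.DataFrame(
        profile.selection_proportions,
        index=profile.feature_names,
        columns=[f"lambda_{l:.6g}" for l in profile.lambda_grid],
    )
    prof_df.insert(0, "max_probability", profile.max_probability)
    prof_df.to_csv(out / "stability_profile.csv", float_format="%.12g")
    log.append(f"stability: B={profile.subsamples_B} markers={fits.panel_markers}")
    pd.DataFrame(
        {
            "marker": panel.marker_names,
            "odds_ratio": panel.per_sd_odds_ratios,
            "ci_low": panel.ci_95[:, 0],
            "ci_high": panel.ci_95[:, 1],
            "p": panel.p_values,
        }
    ).to_csv(out / "panel.csv", index=False, float_format="%.12g")
    prot_d, prot_v = fits.prot_disc, fits.prot_val
    retained = fits.pheno_retained
    log.append(f"stepwise: retained {len(retained)}/{sim.n_pheno} -> {retained}")
    pheno_d, pheno_v = fits.pheno_disc, fits.pheno_val
    geno_design_d, geno_design_v = fits.genomic_design_disc, fits.genomic_design_val
    geno_d, geno_v = fits.geno_disc, fits.geno_val

    # --- scores CSV ------------------------------------------------------
    scores = pd.DataFrame(
        {
            "sample_id": np.concatenate([cohort.sample_id[disc], cohort.sample_id[val]]),
            "cohort": ["discovery"] * int(disc.sum()) + ["validation"] * int(val.sum()),
            "genomic": np.concatenate([geno_d, geno_v]),
            "phenomic": np.concatenate([pheno_d, pheno_v]),
            "proteomic": np.concatenate([prot_d, prot_v]),
        }
    )
    scores.to_csv(out / "scores.csv", index=False, float_format="%.12g")

    # --- model grid ------------------------------------------------------
    grid_rows = model_grid(
        geno_design_d,
        geno_design_v,
        (pheno_d, pheno_v),
        (prot_d, prot_v),
        y_d,
        y_v,
        bootstrap_replicates=config.grid_bootstrap_replicates,
        seed=stage_seed("model_grid"),
    )
    grid = grid_to_frame(grid_rows)
    grid.to_csv(out / "model_grid.csv", index=False, float_format="%.12g")
    log.append("model_grid: " + ", ".join(f"{r.combination}={r.discovery_auc:.3f}" for r in grid_rows))

    # --- bootstrap 80/20 verification on the proteomic panel -------------
    Z_panel = np.column_stack([prot_d, pheno_d, geno_d])
    bv = bootstrap_split_verification(
        logistic_fit_score,
        Z_panel,
        y_d,
        replicates=config.bootstrap_replicates,
        train_fraction=config.train_fraction,
        seed=stage_seed("bootstrap"),
        threshold_rule=config.threshold_rule,
    )
    pd.DataFrame(
        {"sensitivity": bv.sensitivities, "specificity": bv.specificities}
    ).to_csv(out / "bootstrap.csv", index=False, float_format="%.12g")
    log.append(
        f"bootstrap: sens CI=({bv.ci_sensitivity[0]:.3f},{bv.ci_sensitivity[1]:.3f}) "
        f"spec CI=({bv.ci_specificity[0]:.3f},{bv.ci_specificity[1]:.3f}) "
        f"redrawn={bv.redrawn}"
    )

    # --- 10-fold CV on the 3-domain stack --------------------------------
    cv_auc, per_fold = kfold_cv_auc(
        logistic_fit_score, Z_panel, y_d, k=config.cv_folds, seed=stage_seed("cv")
    )
    pd.DataFrame(
        {"fold": np.arange(per_fold.size), "auc": per_fold}
    ).to_csv(out / "cv.csv", index=False, float_format="%.12g")
    log.append(f"cv: pooled AUC={cv_auc:.4f}")

    log.append(
        "config: "
        + json.dumps(
            {
                "stability_B": config.stability_B,
                "panel_k": config.panel_k,
                "lambda_points": config.lambda_points,
                "lambda_min_ratio": config.lambda_min_ratio,
                "stepwise_threshold": config.stepwise_threshold,
                "bootstrap_replicates": config.bootstrap_replicates,
                "train_fraction": config.train_fraction,
                "threshold_rule": config.threshold_rule,
                "cv_folds": config.cv_folds,
                "seed": config.seed,
                "lambda_grid": [float(l) for l in profile.lambda_grid],
            }
        )
    )
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return PipelineResult(
        out_dir=out,
        grid=grid,
        retained_pheno=retained,
        panel_markers=fits.panel_markers,
        n_bonferroni=len(screen.significant),
    )
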