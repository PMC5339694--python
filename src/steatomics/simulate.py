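"""Synthetic tri-domain case-control cohort generator.

Emulates the statistical structure the downstream pipeline assumes: a
bariatric-surgery cohort with a PNPLA3-like risk genotype in Hardy–Weinberg
equilibrium, a 4-level histological steatosis grade, 19 clinical (phenomic)
variables and a wide positive-valued serum-proteome matrix with a handful of
planted diagnostic markers.

Generation order (all from one seeded generator, so identical seeds give
bit-identical cohorts):

1. genotypes ~ Binomial(2, risk_allele_freq)  (HWE);
2. binary steatosis from logit p = alpha + beta·(allele count), alpha solved
   numerically so the marginal prevalence matches 1 − P(grade 0);
3. grades 1–3 among cases, multinomial with the renormalized grade marginal;
4. phenome and proteome drawn conditional on case status: signal columns get
   a case mean-shift (continuous / latent log-scale) or a case odds-ratio
   (binary); proteome noise is block-equicorrelated then exponentiated;
5. genotype_missing_n genotypes masked completely at random;
6. a random discovery/validation split of fixed sizes.

Markers are generated conditional on disease (diagnostic direction), not
causally: the pipeline treats proteins as markers of steatosis, and this
makes the planted sign pattern directly encodable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .config import SimulationConfig

__all__ = ["SyntheticCohort", "generate_cohort", "solve_intercept"]

GENOTYPE_CODES = {0: "CC", 1: "CG", 2: "GG"}


@dataclass
class SyntheticCohort:
    """A generated cohort; the universal input of the pipeline.

    ``genotype`` is the risk-allele count (0/1/2) with -1 for missing.
    ``truth`` records the planted-signal annotations used to generate.
    """

    sample_id: np.ndarray  # str array
    cohort: np.ndarray  # "discovery" / "validation"
    genotype: np.ndarray  # int, -1 = missing
    steatosis_grade: np.ndarray  # 0..3
    steatosis_binary: np.ndarray  # 0/1
    phenome: np.ndarray  # (n, n_pheno)
    pheno_names: list[str]
    proteome: np.ndarray  # (n, n_proteins), positive
    protein_names: list[str]
    truth: dict
    config: SimulationConfig

    @property
    def n(self) -> int:
        return self.sample_id.size

    def mask(self, which: str) -> np.ndarray:
        return self.cohort == which

    def genotype_symbols(self) -> np.ndarray:
        """Genotypes as CC/CG/GG strings with 'NA' for missing."""
        return np.array(
            [GENOTYPE_CODES.get(g, "NA") if g >= 0 else "NA" for g in self.genotype]
        )


def solve_intercept(
    beta: float, allele_probs: np.ndarray, prevalence: float
) -> float:
    """Solve alpha so that E_g[expit(alpha + beta·g)] equals ``prevalence``.

    Raises with the offending values when the prevalence is infeasible.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} must lie strictly in (0, 1)")
    g = np.arange(allele_probs.size)

    def marginal(a: float) -> float:
        return float(allele_probs @ expit(a + beta * g)) - prevalence

    lo, hi = -50.0, 50.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ValueError(
            f"cannot calibrate intercept: prevalence={prevalence}, "
            f"per-allele log-odds={beta}"
        )
    return float(brentq(marginal, lo, hi, xtol=1e-12))


def _block_correlated_normal(
    rng: np.random.Generator, n: int, p: int, rho: float, block: int
) -> np.ndarray:
    """(n, p) standard normals, equicorrelated rho inside blocks of ``block``."""
    eps = rng.standard_normal((n, p))
    if rho <= 0:
        return eps
    n_blocks = -(-p // block)
    shared = rng.standard_normal((n, n_blocks))
    shared_full = np.repeat(shared, block, axis=1)[:, :p]
    return np.sqrt(rho) * shared_full + np.sqrt(1.0 - rho) * eps


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one synthetic cohort under ``config`` (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    q = config.risk_allele_freq

    # 1. genotypes in HWE
    genotype = rng.binomial(2, q, size=n)

    # 2. binary steatosis with calibrated marginal prevalence
    allele_probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    alpha = solve_intercept(config.per_allele_log_odds, allele_probs, config.prevalence)
    p_case = expit(alpha + config.per_allele_log_odds * genotype)
    steatosis = (rng.random(n) < p_case).astype(int)

    # 3. grades among cases
    grade = np.zeros(n, dtype=int)
    case_idx = np.nonzero(steatosis == 1)[0]
    gp = np.asarray(config.grade_probs[1:], dtype=float)
    gp = gp / gp.sum()
    grade[case_idx] = rng.choice([1, 2, 3], size=case_idx.size, p=gp)

    # 4a. phenome
    n_bin = config.n_pheno_binary
    n_cont = config.n_pheno - n_bin
    phenome = np.empty((n, config.n_pheno))
    phenome[:, :n_cont] = rng.standard_normal((n, n_cont))
    base = config.pheno_binary_base_prev
    for sig in config.signal_pheno:
        if sig.kind == "continuous":
            phenome[case_idx, sig.index] += sig.effect
    # binary columns: control prevalence `base`, case prevalence via odds ratio
    for j in range(n_cont, config.n_pheno):
        sig = next(
            (s for s in config.signal_pheno if s.index == j and s.kind == "binary"),
            None,
        )
        pj = np.full(n, base)
        if sig is not None:
            odds_case = sig.effect * base / (1.0 - base)
            pj[case_idx] = odds_case / (1.0 + odds_case)
        phenome[:, j] = (rng.random(n) < pj).astype(float)

    # 4b. proteome: block-correlated latent normals, case shifts, exponentiate
    latent = _block_correlated_normal(
        rng, n, config.n_proteins, config.protein_block_rho, config.protein_block_size
    )
    for sig in config.signal_proteins:
        latent[case_idx, sig.index] += sig.direction * sig.shift_sd
    proteome = np.exp(latent)

    # 5. missing genotypes, completely at random
    miss = rng.choice(n, size=config.genotype_missing_n, replace=False)
    genotype = genotype.copy()
    genotype[miss] = -1

    # 6. cohort split
    perm = rng.permutation(n)
    cohort = np.empty(n, dtype=object)
    cohort[perm[: config.discovery_n]] = "discovery"
    cohort[perm[config.discovery_n :]] = "validation"
    cohort = cohort.astype(str)

    width = len(str(n))
    sample_id = np.array([f"S{i:0{width}d}" for i in range(1, n + 1)])
    truth = {
        "alpha": alpha,
        "per_allele_log_odds": config.per_allele_log_odds,
        "signal_proteins": [
            {"index": s.index, "direction": s.direction, "shift_sd": s.shift_sd}
            for s in config.signal_proteins
        ],
        "signal_pheno": [
            {"index": s.index, "kind": s.kind, "effect": s.effect}
            for s in config.signal_pheno
        ],
        "seed": config.seed,
    }
    return SyntheticCohort(
        sample_id=sample_id,
        cohort=cohort,
        genotype=genotype,
        steatosis_grade=grade,
        steatosis_binary=steatosis,
        phenome=phenome,
        pheno_names=[f"pheno_{j:02d}" for j in range(config.n_pheno)],
        proteome=proteome,
        protein_names=[f"prot_{j:04d}" for j in range(config.n_proteins)],
        truth=truth,
        config=config,
    )
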