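"""Proteomic marker discovery: Bonferroni screening and stability selection.

Stability selection repeatedly draws class-stratified half-subsamples of the
cohort, fits the L1-logistic path on each over a shared decreasing lambda
grid, and records for every protein the proportion of subsamples in which the
lasso selects it at each lambda.  A protein's stability score is the maximum
of that selection proportion over the grid, and markers are ranked by it.

The univariate Bonferroni screen is reported alongside as a parallel
analysis; by default it does NOT pre-filter stability selection (a flag flips
the ordering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import fit_logistic_mle
from .lasso import lasso_logistic_path, make_lambda_grid

__all__ = [
    "StabilityProfile",
    "MarkerSet",
    "bonferroni_screen",
    "stability_paths",
    "select_stable_markers",
    "log_standardize",
]


def log_standardize(proteome: np.ndarray) -> np.ndarray:
    """log-transform a positive abundance matrix and standardize each column.

    Aptamer abundances are positive and right-skewed; the per-SD odds ratios
    of the fitted panel presuppose mean-0 / SD-1 inputs.
    """
    X = np.asarray(proteome, dtype=float)
    if np.any(X <= 0):
        raise ValueError("proteome entries must be strictly positive")
    L = np.log(X)
    mu = L.mean(axis=0)
    sd = L.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (L - mu) / sd


@dataclass
class StabilityProfile:
    """Per-feature selection proportions over subsamples and the lambda grid."""

    feature_names: list[str]
    lambda_grid: np.ndarray  # (L,) decreasing
    selection_proportions: np.ndarray  # (p, L) in [0, 1]
    subsamples_B: int
    sample_fraction: float
    seed: int | None

    @property
    def max_probability(self) -> np.ndarray:
        """Row-wise maximum selection proportion (the stability score)."""
        return self.selection_proportions.max(axis=1)

    @property
    def mean_proportion(self) -> np.ndarray:
        return self.selection_proportions.mean(axis=1)


@dataclass
class MarkerSet:
    """Stability-ranked markers: names with non-increasing stability scores."""

    selected: list[str]
    scores: np.ndarray


@dataclass
class ScreenResult:
    feature_names: list[str]
    p_values: np.ndarray
    threshold: float
    significant: list[str]


def bonferroni_screen(
    proteome: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    feature_names: list[str] | None = None,
    already_standardized: bool = False,
) -> ScreenResult:
    """Univariate likelihood-ratio screen of each protein at alpha/p.

    Each protein (log-transformed, standardized) is tested by the 1-df
    likelihood-ratio test of the univariate logistic model against the
    intercept-only model.  Constant proteins get p = 1 with a warning.
    """
    y = np.asarray(labels, dtype=float).ravel()
    Z = np.asarray(proteome, float) if already_standardized else log_standardize(proteome)
    n, p = Z.shape
    names = feature_names or [f"prot_{j:04d}" for j in range(p)]
    null = fit_logistic_mle(np.empty((n, 0)), y)
    pvals = np.ones(p)
    for j in range(p):
        col = Z[:, j]
        if col.std() < 1e-12:
            warnings.warn(f"constant protein column {names[j]}; p set to 1", stacklevel=2)
            continue
        fit = fit_logistic_mle(col[:, None], y, column_names=[names[j]])
        lr = 2.0 * (fit.log_likelihood - null.log_likelihood)
        pvals[j] = stats.chi2.sf(max(lr, 0.0), 1)
    thr = alpha / p
    sig = [names[j] for j in range(p) if pvals[j] < thr]
    return ScreenResult(names, pvals, thr, sig)


def stability_paths(
    proteome: np.ndarray,
    labels: np.ndarray,
    B: int = 100,
    fraction: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    already_standardized: bool = False,
    prefilter_names: list[str] | None = None,
) -> StabilityProfile:
    """Half-subsample stability selection with the L1-logistic kernel.

    Draws ``B`` class-stratified subsamples of ``floor(fraction*n)`` samples
    without replacement, fits the lasso path on each over a shared lambda
    grid (default: 30 log-spaced points from the full-data lambda_max down to
    1% of it), and tallies per-feature selection proportions.

    ``prefilter_names`` optionally restricts the candidate set (e.g. to the
    Bonferroni-significant proteins); excluded features keep all-zero rows so
    the profile shape is stable.
    """
    if B < 1:
        raise ValueError("need at least one subsample")
    y = np.asarray(labels, dtype=float).ravel()
    Z = np.asarray(proteome, float) if already_standardized else log_standardize(proteome)
    n, p = Z.shape
    names = list(feature_names or [f"prot_{j:04d}" for j in range(p)])
    cand = np.arange(p)
    if prefilter_names is not None:
        keep = {nm for nm in prefilter_names}
        cand = np.array([j for j in range(p) if names[j] in keep], dtype=int)
        if cand.size == 0:
            raise ValueError("prefilter removed every feature")
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(Z[:, cand], y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    cases = np.nonzero(y == 1)[0]
    ctrls = np.nonzero(y == 0)[0]
    n_sub = int(np.floor(fraction * n))
    n_case_sub = int(round(fraction * cases.size))
    n_ctrl_sub = n_sub - n_case_sub
    if n_case_sub < 1 or n_ctrl_sub < 1:
        raise ValueError("a stratified subsample would contain a single class")

    rng = np.random.default_rng(seed)
    counts = np.zeros((p, lambda_grid.size), dtype=np.int64)
    Zc = np.ascontiguousarray(Z[:, cand])
    for _b in range(B):
        sub = np.concatenate(
            [
                rng.choice(cases, size=n_case_sub, replace=False),
                rng.choice(ctrls, size=n_ctrl_sub, replace=False),
            ]
        )
        ysub = y[sub]
        if ysub.min() == ysub.max():  # unreachable under stratification
            raise RuntimeError("subsample with a single class")
        path = lasso_logistic_path(Zc[sub], ysub, lambda_grid)
        counts[cand] += (path.coefficients != 0.0).astype(np.int64)
    return StabilityProfile(
        feature_names=names,
        lambda_grid=lambda_grid,
        selection_proportions=counts / float(B),
        subsamples_B=B,
        sample_fraction=fraction,
        seed=seed,
    )


def select_stable_markers(profile: StabilityProfile, k: int = 8) -> MarkerSet:
    """Top-k features by maximum selection probability.

    Ties break by larger mean selection proportion over the grid, then by
    feature name, so the output is deterministic.  Features with zero
    stability are never selected; if fewer than ``k`` have positive scores,
    all of them are returned with a warning.
    """
    p = len(profile.feature_names)
    if k > p:
        raise ValueError(f"k={k} exceeds the number of features ({p})")
    maxp = profile.max_probability
    meanp = profile.mean_proportion
    order = sorted(
        range(p),
        key=lambda j: (-maxp[j], -meanp[j], profile.feature_names[j]),
    )
    order = [j for j in order if maxp[j] > 0.0]
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} features with positive stability (k={k} requested)",
            stacklevel=2,
        )
    top = order[:k]
    return MarkerSet(
        selected=[profile.feature_names[j] for j in top],
        scores=maxp[top],
    )
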