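"""Maximum-likelihood logistic regression via iteratively reweighted least squares.

This is the shared numerical engine for every domain classifier: the phenomic
stepwise search, the standardized proteomic panel, the genomic genotype model
and the second-level stacking models are all plain Bernoulli GLM fits produced
here.  The fitter is deliberately self-contained (no statsmodels dependency)
because the stepwise search and the stability-selection engine need tight
control over convergence handling: quasi-separated fits must come back with
``converged=False`` and a capped coefficient norm instead of raising, so that
greedy model searches never crash mid-path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["DesignMatrix", "FittedLogit", "fit_logistic_mle"]

# Coefficient-norm guard: beyond this the likelihood is flat to machine
# precision and the data are treated as (quasi-)separated.
_NORM_CAP = 1e3


@dataclass
class DesignMatrix:
    """A dense predictor matrix with named columns (intercept excluded).

    Parameters
    ----------
    values:
        ``(n, p)`` float array; must be finite.
    column_names:
        Length-``p`` list of unique column identifiers.
    intercept_included:
        Whether models built on this design should include an intercept
        (always true for every analysis in this package; exposed for
        completeness).
    """

    values: np.ndarray
    column_names: list[str]
    intercept_included: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.column_names = list(self.column_names)
        if self.values.shape[1] != len(self.column_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.column_names)} column names"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("duplicate column names in design matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def drop(self, name: str) -> "DesignMatrix":
        """Return a copy without column ``name``."""
        j = self.column_names.index(name)
        keep = [i for i in range(self.p) if i != j]
        return DesignMatrix(
            self.values[:, keep],
            [self.column_names[i] for i in keep],
            self.intercept_included,
        )

    def select(self, names: list[str]) -> "DesignMatrix":
        idx = [self.column_names.index(n) for n in names]
        return DesignMatrix(self.values[:, idx], list(names), self.intercept_included)


@dataclass
class FittedLogit:
    """A fitted logistic regression model.

    ``coefficients`` are on the scale of the design columns as passed in;
    callers that standardize inputs are responsible for storing their own
    standardization parameters (see ``PanelModel``).
    """

    intercept: float
    coefficients: np.ndarray
    column_names: list[str]
    standard_errors: np.ndarray | None
    log_likelihood: float
    converged: bool
    iterations: int
    intercept_se: float | None = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-sample predicted probability of the positive class."""
        return expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(zip(self.column_names, map(float, self.coefficients))),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
        }


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_mle(
    design: DesignMatrix | np.ndarray,
    labels: np.ndarray,
    tolerance: float = 1e-8,
    max_iterations: int = 100,
    column_names: list[str] | None = None,
) -> FittedLogit:
    """Fit a logistic regression by IRLS with step-halving.

    Parameters
    ----------
    design:
        ``DesignMatrix`` or raw ``(n, p)`` array (``p`` may be 0 for an
        intercept-only fit).
    labels:
        0/1 outcome vector with both classes present.
    tolerance:
        Convergence declared when the score (gradient) max-norm falls below
        this value.
    max_iterations:
        IRLS iteration cap; on quasi-separation the coefficient norm is
        capped at 1e3 and the fit returns with ``converged=False``.

    Raises
    ------
    ValueError
        If labels are single-class, or the design (with intercept) is rank
        deficient — the error names the offending columns.
    """
    if isinstance(design, DesignMatrix):
        X = design.values
        names = design.column_names
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = column_names or [f"x{j}" for j in range(X.shape[1])]

    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and labels have different lengths")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be coded 0/1")
    if classes.size < 2:
        raise ValueError("labels contain a single class; cannot fit a classifier")

    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])

    # Rank check with named columns
    if p > 0:
        _, sv, vt = np.linalg.svd(Xa, full_matrices=False)
        if sv[-1] < 1e-10 * sv[0]:
            null = np.abs(vt[-1])
            bad = [(["(intercept)"] + names)[j] for j in np.nonzero(null > 1e-8)[0]]
            raise ValueError(
                "design matrix is rank deficient; dependent columns: "
                + ", ".join(bad)
            )

    beta = np.zeros(p + 1)
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))  # warm start at null model
    eta = Xa @ beta
    ll = _bernoulli_loglik(eta, y)
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        mu = expit(eta)
        grad = Xa.T @ (y - mu)
        if np.max(np.abs(grad)) < tolerance:
            converged = True
            break
        w = mu * (1.0 - mu)
        # Fisher information; ridge epsilon only as a numerical floor for
        # nearly-separated fits (does not move interior solutions).
        H = (Xa * w[:, None]).T @ Xa
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee likelihood ascent
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = Xa @ cand
            ll_c = _bernoulli_loglik(eta_c, y)
            if ll_c >= ll - 1e-12:
                beta, eta, ll = cand, eta_c, ll_c
                break
            t *= 0.5
        if np.linalg.norm(beta) > _NORM_CAP:
            beta *= _NORM_CAP / np.linalg.norm(beta)
            eta = Xa @ beta
            ll = _bernoulli_loglik(eta, y)
            converged = False
            break

    if converged:
        # a vanishing gradient can also be reached by (quasi-)separation,
        # where the MLE does not exist; flag it rather than report a fit
        mu = expit(eta)
        sep = np.all(np.abs(y - mu) < 1e-8) and np.any(np.abs(beta[1:]) > 10)
        if sep:
            converged = False

    se = None
    se0 = None
    if converged:
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = (Xa * w[:, None]).T @ Xa
        try:
            cov = np.linalg.inv(H)
            d = np.sqrt(np.diag(cov))
            se0, se = float(d[0]), d[1:]
        except np.linalg.LinAlgError:
            pass

    return FittedLogit(
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        column_names=list(names),
        standard_errors=se,
        log_likelihood=ll,
        converged=converged,
        iterations=it,
        intercept_se=se0,
    )
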