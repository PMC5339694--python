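"""L1-penalized logistic regression paths by cyclic coordinate descent.

Objective (per grid point): mean negative Bernoulli log-likelihood plus
``lambda * ||beta||_1`` with an unpenalized intercept.  Columns are
standardized internally to mean 0 / SD 1 and coefficients are reported on the
standardized scale; the mean-NLL convention makes lambda comparable across
sample sizes, which is what lets a single lambda grid be shared across the
half-subsamples of stability selection.

The solver is a proximal-Newton coordinate descent in the glmnet style: an
outer loop forms the weighted quadratic approximation of the log-likelihood
at the current iterate (weights p(1−p) floored at 1e-5), an inner cyclic
coordinate descent soft-thresholds the active set on that quadratic, and a
full sweep over the true logistic gradient admits KKT violators into the
active set, warm-started along the decreasing lambda grid.  The kernel is
numba-compiled; KKT residuals are checked to 1e-4 at every grid point (see
the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .glm import DesignMatrix

__all__ = ["LassoPath", "lasso_logistic_path", "lambda_max", "make_lambda_grid"]


@dataclass
class LassoPath:
    """Coefficient paths over a decreasing lambda grid (standardized scale)."""

    lambda_grid: np.ndarray  # (L,) strictly decreasing, positive
    coefficients: np.ndarray  # (p, L)
    intercepts: np.ndarray  # (L,)
    column_names: list[str]
    center: np.ndarray  # (p,) per-column means used internally
    scale: np.ndarray  # (p,) per-column SDs (1.0 for constant columns)

    def active_set(self, l: int) -> list[str]:
        """Names of features with nonzero coefficient at grid point ``l``."""
        return [
            self.column_names[j]
            for j in np.nonzero(self.coefficients[:, l] != 0.0)[0]
        ]

    @property
    def n_active(self) -> np.ndarray:
        return (self.coefficients != 0.0).sum(axis=0)


@njit(cache=True)
def _cd_logistic_path(XT, y, lambdas, tol, max_outer):  # pragma: no cover - jit
    # XT is (p, n) C-contiguous so each feature row is a contiguous slice.
    p, n = XT.shape
    L = lambdas.shape[0]
    coefs = np.zeros((p, L))
    icepts = np.zeros(L)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    active = np.zeros(p, np.bool_)
    w = np.empty(n)
    z = np.empty(n)  # working response of the quadratic approximation
    res = np.empty(n)  # its residual z - (b0 + X beta)
    for li in range(L):
        lam = lambdas[li]
        for _outer in range(max_outer):
            # quadratic approximation at the current (b0, beta)
            wsum = 0.0
            for i in range(n):
                pr = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = pr * (1.0 - pr)
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = wi
                res[i] = (y[i] - pr) / wi
                z[i] = eta[i] + res[i]
                wsum += wi
            # inner coordinate descent on the penalized weighted LS problem
            for _inner in range(200):
                delta_max = 0.0
                for j in range(p):
                    if not active[j]:
                        continue
                    xj = XT[j]
                    num = 0.0
                    den = 0.0
                    for i in range(n):
                        wx = w[i] * xj[i]
                        num += wx * res[i]
                        den += wx * xj[i]
                    den /= n
                    zj = num / n + den * beta[j]
                    if zj > lam:
                        new = (zj - lam) / den
                    elif zj < -lam:
                        new = (zj + lam) / den
                    else:
                        new = 0.0
                    d = new - beta[j]
                    if d != 0.0:
                        beta[j] = new
                        for i in range(n):
                            res[i] -= xj[i] * d
                        if new == 0.0:
                            active[j] = False
                        if abs(d) > delta_max:
                            delta_max = abs(d)
                # unpenalized intercept on the quadratic
                num0 = 0.0
                for i in range(n):
                    num0 += w[i] * res[i]
                d0 = num0 / wsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        res[i] -= d0
                    if abs(d0) > delta_max:
                        delta_max = abs(d0)
                if delta_max < 0.1 * tol:
                    break
            # eta = b0 + X beta follows from the quadratic bookkeeping
            # (z was built around the previous eta); then check KKT on the
            # true logistic gradient, admitting violators into the active set
            r_mean = 0.0
            rvec = np.empty(n)
            for i in range(n):
                eta[i] = z[i] - res[i]
                pr = 1.0 / (1.0 + np.exp(-eta[i]))
                rvec[i] = y[i] - pr
                r_mean += rvec[i]
            r_mean /= n
            kkt_ok = abs(r_mean) <= 0.25 * tol
            grad = np.dot(XT, rvec)  # BLAS gemv: the expensive full sweep
            for j in range(p):
                g = grad[j] / n
                if beta[j] == 0.0:
                    if abs(g) > lam + 0.25 * tol:
                        active[j] = True
                        kkt_ok = False
                else:
                    sgn = 1.0 if beta[j] > 0.0 else -1.0
                    if abs(g - lam * sgn) > 0.25 * tol:
                        kkt_ok = False
            if kkt_ok:
                break
        coefs[:, li] = beta
        icepts[li] = b0
    return coefs, icepts


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    const = scale < 1e-12
    scale_safe = np.where(const, 1.0, scale)
    Z = (X - center) / scale_safe
    Z[:, const] = 0.0
    return Z, center, scale_safe, const


def lambda_max(design: DesignMatrix | np.ndarray, labels) -> float:
    """Smallest lambda at which all penalized coefficients are exactly zero.

    For standardized columns, ``lambda_max = max_j |x_jᵀ(y − ȳ)| / n``.
    """
    X = design.values if isinstance(design, DesignMatrix) else np.asarray(design, float)
    y = np.asarray(labels, dtype=float).ravel()
    Z, _, _, _ = _standardize(X)
    return float(np.max(np.abs(Z.T @ (y - y.mean()))) / y.size)


def make_lambda_grid(
    design: DesignMatrix | np.ndarray,
    labels,
    n_points: int = 30,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(design, labels)
    if lmax <= 0:
        raise ValueError("lambda_max is zero: labels are constant or design is empty")
    return np.geomspace(lmax, min_ratio * lmax, n_points)


def lasso_logistic_path(
    design: DesignMatrix | np.ndarray,
    labels,
    lambda_grid,
    tolerance: float = 1e-5,
    max_sweeps: int = 200,
    column_names: list[str] | None = None,
) -> LassoPath:
    """Fit the L1-logistic coefficient path over a decreasing lambda grid.

    Raises on a non-decreasing or non-positive grid; constant columns are
    pinned to coefficient 0 with a warning.
    """
    if isinstance(design, DesignMatrix):
        X = design.values
        names = design.column_names
    else:
        X = np.asarray(design, dtype=float)
        names = column_names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=float).ravel()
    lambdas = np.asarray(lambda_grid, dtype=float).ravel()
    if lambdas.size == 0 or np.any(lambdas <= 0):
        raise ValueError("lambda grid must be positive")
    if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    if y.min() == y.max():
        raise ValueError("labels contain a single class")

    Z, center, scale, const = _standardize(X)
    if const.any():
        bad = [names[j] for j in np.nonzero(const)[0]]
        warnings.warn(
            "constant columns pinned to coefficient 0: " + ", ".join(bad),
            stacklevel=2,
        )
    coefs, icepts = _cd_logistic_path(
        np.ascontiguousarray(Z.T), y, lambdas, tolerance, max_sweeps
    )
    coefs[const, :] = 0.0
    return LassoPath(
        lambda_grid=lambdas,
        coefficients=coefs,
        intercepts=icepts,
        column_names=list(names),
        center=center,
        scale=scale,
    )
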