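"""Prior knowledge in the filtering update.

Two mechanisms are provided:

* **L1-penalized MAP update.**  The Kalman filtered mean is the minimizer
  of the quadratic cost ``J(xbar) = (y - B xbar)' R^-1 (y - B xbar) +
  (xbar - xhat)' P^-1 (xbar - xhat)``.  Sparsity or known-non-edge priors
  add a weighted L1 term ``||lam o xbar||_1`` on the coefficient block,
  and the penalized minimizer is found by iterative soft thresholding
  with Barzilai-Borwein step sizes.

* **PDF truncation for range constraints.**  Componentwise bounds
  ``c <= xbar <= d`` are enforced sequentially by truncating, for each
  bound, the Gaussian belief along the constrained coordinate and
  replacing it with the truncated-normal mean and variance.

Both produce a (pseudo) mean/covariance that feeds the next prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm, truncnorm

from .filters import GaussianBelief, MeasurementModel, update_linear
from .model import augmented_dim

__all__ = [
    "PenaltySpec",
    "RangeConstraint",
    "map_cost",
    "map_gradient",
    "soft_threshold",
    "bb_step",
    "iterative_thresholding_update",
    "truncated_normal_moments",
    "apply_range_constraints",
]

logger = logging.getLogger(__name__)

# BB step-size clamp and fallback
_ALPHA_MIN, _ALPHA_MAX = 1e-8, 1e8


@dataclass(frozen=True)
class PenaltySpec:
    """Per-component L1 weights on the augmented state.

    ``lam`` is zero on the expression and steepness blocks in every
    shipped mode; only regulatory coefficients are penalized.
    """

    lam: NDArray[np.float64]
    mode: Literal["lasso", "indicator", "weighted-indicator"]
    lambda_scalar: float
    E: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        if np.any(self.lam < 0):
            raise ValueError("penalty weights must be nonnegative")

    @staticmethod
    def lasso(n: int, lambda_scalar: float) -> "PenaltySpec":
        """Uniform LASSO weight on all n^2 coefficients."""
        lam = np.zeros(augmented_dim(n))
        lam[n : n + n * n] = lambda_scalar
        return PenaltySpec(lam=lam, mode="lasso", lambda_scalar=lambda_scalar)

    @staticmethod
    def indicator(E: NDArray[np.float64], lambda_scalar: float) -> "PenaltySpec":
        """Penalty ``lambda * e_ij`` on coefficient a_ij.

        ``e_ij = 1`` marks "gene j is believed not to regulate gene i";
        larger values encode stronger belief (weighted-indicator mode).
        """
        E = np.asarray(E, dtype=float)
        n = E.shape[0]
        if E.shape != (n, n):
            raise ValueError("E must be square")
        if np.any(E < 0):
            raise ValueError("E must be nonnegative")
        lam = np.zeros(augmented_dim(n))
        lam[n : n + n * n] = lambda_scalar * E.ravel(order="C")
        binary = np.all(np.isin(E, (0.0, 1.0)))
        mode = "indicator" if binary else "weighted-indicator"
        return PenaltySpec(lam=lam, mode=mode, lambda_scalar=lambda_scalar, E=E)


@dataclass(frozen=True)
class RangeConstraint:
    """Componentwise bounds ``lower <= xbar <= upper`` (infinite allowed)."""

    lower: NDArray[np.float64]
    upper: NDArray[np.float64]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be equal-length vectors")
        if np.any(lo > hi):
            raise ValueError("lower bounds must not exceed upper bounds")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @staticmethod
    def on_coefficients(
        n: int,
        tight_mask: NDArray[np.bool_] | None = None,
        tight: float = 0.1,
        loose: float = 10.0,
    ) -> "RangeConstraint":
        """Symmetric bounds on the coefficient block only.

        Coefficients flagged by ``tight_mask`` (an n x n boolean matrix)
        get ``±tight``, the rest ``±loose``; expression levels and
        steepness parameters stay unbounded.
        """
        d = augmented_dim(n)
        lo = np.full(d, -np.inf)
        hi = np.full(d, np.inf)
        bound = np.full(n * n, loose)
        if tight_mask is not None:
            bound[np.asarray(tight_mask, dtype=bool).ravel(order="C")] = tight
        lo[n : n + n * n] = -bound
        hi[n : n + n * n] = bound
        return RangeConstraint(lower=lo, upper=hi)


def _chol_with_jitter(P: NDArray[np.float64]):
    try:
        return cho_factor(P, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(np.trace(P), 1e-300) / P.shape[0]
        return cho_factor(P + jitter * np.eye(P.shape[0]), lower=True)


def map_cost(
    xbar: NDArray[np.float64],
    y: NDArray[np.float64],
    predicted: GaussianBelief,
    model: MeasurementModel,
) -> float:
    """Quadratic MAP cost whose minimizer is the Kalman filtered mean."""
    cR = _chol_with_jitter(model.R)
    cP = _chol_with_jitter(predicted.cov)
    ry = y - model.B @ xbar
    rx = xbar - predicted.mean
    return float(ry @ cho_solve(cR, ry) + rx @ cho_solve(cP, rx))


def map_gradient(
    xbar: NDArray[np.float64],
    y: NDArray[np.float64],
    predicted: GaussianBelief,
    model: MeasurementModel,
) -> NDArray[np.float64]:
    """Gradient of :func:`map_cost`: ``-2 B'R^-1(y - Bx) + 2 P^-1(x - xhat)``."""
    cR = _chol_with_jitter(model.R)
    cP = _chol_with_jitter(predicted.cov)
    ry = y - model.B @ xbar
    rx = xbar - predicted.mean
    return -2.0 * model.B.T @ cho_solve(cR, ry) + 2.0 * cho_solve(cP, rx)


def soft_threshold(u: NDArray[np.float64], a) -> NDArray[np.float64]:
    """Componentwise shrinkage ``sign(u) max(|u| - a, 0)``."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("threshold must be nonnegative")
    u = np.asarray(u, dtype=float)
    return np.sign(u) * np.maximum(np.abs(u) - a, 0.0)


def bb_step(
    s: NDArray[np.float64],
    r: NDArray[np.float64],
    fallback: float = 1.0,
) -> float:
    """Barzilai-Borwein curvature estimate ``(s'r) / ||s||^2``, clamped.

    Degenerate inputs (zero step or nonpositive curvature) fall back to
    ``fallback``.
    """
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    ss = float(s @ s)
    sr = float(s @ r)
    if ss <= 0.0 or sr <= 0.0:
        return float(np.clip(fallback, _ALPHA_MIN, _ALPHA_MAX))
    return float(np.clip(sr / ss, _ALPHA_MIN, _ALPHA_MAX))


def iterative_thresholding_update(
    predicted: GaussianBelief,
    y: NDArray[np.float64],
    model: MeasurementModel,
    penalty: PenaltySpec,
    eps: float = 1e-6,
    max_iter: int = 500,
) -> NDArray[np.float64]:
    """L1-penalized filtered mean by proximal-gradient iteration.

    Minimizes ``map_cost(xbar) + ||lam o xbar||_1`` starting from the
    unpenalized Kalman mean.  Each iteration takes a gradient step of
    size 1/alpha and soft-thresholds by ``lam/alpha``; alpha comes from
    the Barzilai-Borwein formula, safeguarded by doubling alpha until the
    penalized objective does not increase.  Stops when the relative
    objective change drops below ``eps``.
    """
    lam = penalty.lam
    d = predicted.dim
    if lam.shape != (d,):
        raise ValueError("penalty length does not match state dimension")
    y = np.asarray(y, dtype=float)

    cR = _chol_with_jitter(model.R)
    cP = _chol_with_jitter(predicted.cov)
    B = model.B

    def grad(x):
        return -2.0 * B.T @ cho_solve(cR, y - B @ x) + 2.0 * cho_solve(
            cP, x - predicted.mean
        )

    def smooth(x):
        ry = y - B @ x
        rx = x - predicted.mean
        return float(ry @ cho_solve(cR, ry) + rx @ cho_solve(cP, rx))

    def objective(x):
        return smooth(x) + float(lam @ np.abs(x))

    # warm start at the unpenalized optimum
    x = update_linear(predicted, y, model).filtered.mean.copy()
    g = grad(x)
    # Hessian-scale initial step: trace of 2(B'R^-1 B + P^-1)) / d
    tr_Rinv = float(np.trace(cho_solve(cR, np.eye(model.R.shape[0]))))
    tr_Pinv = float(np.trace(cho_solve(cP, np.eye(d))))
    alpha = max(2.0 * (tr_Rinv + tr_Pinv) / d, _ALPHA_MIN)

    J = objective(x)
    for _ in range(max_iter):
        x_new = soft_threshold(x - g / alpha, lam / alpha)
        J_new = objective(x_new)
        # safeguard: enlarge alpha (smaller step) until no increase
        while J_new > J + 1e-12 * max(abs(J), 1.0) and alpha < _ALPHA_MAX:
            alpha = min(alpha * 2.0, _ALPHA_MAX)
            x_new = soft_threshold(x - g / alpha, lam / alpha)
            J_new = objective(x_new)
        g_new = grad(x_new)
        s = x_new - x
        r = g_new - g
        converged = abs(J_new - J) <= eps * max(abs(J), 1e-300)
        x, g, J_prev, J = x_new, g_new, J, J_new
        if converged:
            break
        alpha = bb_step(s, r, fallback=alpha)
    else:
        logger.warning(
            "iterative thresholding: max_iter=%d reached (rel. change %.2e)",
            max_iter,
            abs(J - J_prev) / max(abs(J_prev), 1e-300),
        )
    return x


def truncated_normal_moments(c_t: float, d_t: float) -> tuple[float, float]:
    """Mean and variance of a standard normal truncated to [c_t, d_t]."""
    if not c_t < d_t:
        raise ValueError("lower truncation bound must be below the upper")
    mass = norm.cdf(d_t) - norm.cdf(c_t)
    if not np.isfinite(mass) or mass < 1e-300:
        # both bounds deep in one tail; fall back to the survival-function
        # difference before declaring the interval empty
        mass = abs(norm.sf(c_t) - norm.sf(d_t))
        if mass < 1e-300:
            raise ValueError(
                f"truncation interval [{c_t}, {d_t}] has negligible probability mass"
            )
    m, v = truncnorm.stats(c_t, d_t, moments="mv")
    return float(m), float(v)


def apply_range_constraints(
    belief: GaussianBelief,
    rc: RangeConstraint,
    mass_sigma: float = 8.5,
) -> GaussianBelief:
    """Sequential PDF truncation of a Gaussian belief to componentwise bounds.

    Constraints are enforced in ascending component order.  For each
    component with a finite bound, the covariance is eigendecomposed,
    the belief is rotated so the constrained direction becomes the first
    coordinate (orthogonal completion of the required first row), that
    coordinate's density is replaced by its truncated-normal moments, and
    the transform is inverted.  The result is the pseudo mean/covariance
    used by the next filtering step.

    Bounds further than ``mass_sigma`` standard deviations on both sides
    leave the belief unchanged to machine precision and are skipped.
    """
    mean = belief.mean.copy()
    P = belief.cov.copy()
    d = mean.shape[0]
    if rc.lower.shape != (d,):
        raise ValueError("constraint length does not match belief dimension")

    for i in range(d):
        lo, hi = rc.lower[i], rc.upper[i]
        if np.isinf(lo) and np.isinf(hi):
            continue
        sd = np.sqrt(max(P[i, i], 0.0))
        if sd == 0.0:
            if mean[i] < lo - 1e-12 or mean[i] > hi + 1e-12:
                raise ValueError(
                    f"degenerate component {i} violates its bounds"
                )
            continue
        c_t = (lo - mean[i]) / sd
        d_t = (hi - mean[i]) / sd
        if c_t < -mass_sigma and d_t > mass_sigma:
            continue
        if c_t >= d_t:
            raise ValueError(f"empty feasible interval for component {i}")

        # rotate: z = G D^{-1/2} S' (x - mean) with first row of G D^{1/2} S'
        # proportional to e_i' P
        w, V = np.linalg.eigh(0.5 * (P + P.T))
        w = np.clip(w, 0.0, None)
        sqw = np.sqrt(w)
        r1 = sqw * V[i, :]            # D^{1/2} S' e_i
        r1 /= np.linalg.norm(r1)
        G = _orthogonal_completion(r1)

        mu_t, var_t = truncated_normal_moments(float(c_t), float(d_t))
        zbar = np.zeros(d)
        zbar[0] = mu_t
        Qz = np.eye(d)
        Qz[0, 0] = var_t

        T = (V * sqw) @ G.T           # S D^{1/2} G'
        mean = T @ zbar + mean
        P = T @ Qz @ T.T
        P = 0.5 * (P + P.T)
    return GaussianBelief(mean=mean, cov=P)


def _orthogonal_completion(r1: NDArray[np.float64]) -> NDArray[np.float64]:
    """Orthogonal matrix whose first row is ``r1`` (unit norm).

    Householder reflection mapping e_1 to r1; symmetric, so its first row
    is r1 as required.
    """
    d = r1.shape[0]
    e1 = np.zeros(d)
    e1[0] = 1.0
    v = r1 - e1
    nv = v @ v
    if nv < 1e-30:
        return np.eye(d)
    H = np.eye(d) - 2.0 * np.outer(v, v) / nv
    return H
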