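"""Point-based Gaussian approximation filtering on the augmented GRN state.

The belief over the augmented state ``xbar = [x; vec(A); mu]`` is a
Gaussian ``N(mean, cov)``.  Prediction pushes the belief through the
sigmoid dynamics either with a quadrature rule (UKF / CKF3 / CKF5) or a
first-order linearization (EKF baseline).  Because the measurement model
``y = B xbar + noise`` with ``B = [I_n, 0]`` is linear, the measurement
update is the exact Kalman update.

:func:`run_filter` drives the sequence over a measurement series and
decodes the final parameter estimate; prior-knowledge constraints
(L1-penalized mean, range truncation) plug in per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from numpy.typing import NDArray

from .model import (
    GRNParameters,
    NoiseSpec,
    augmented_dim,
    augmented_dynamics,
    decode_params,
    sigmoid_activation,
)
from .quadrature import (
    QuadraturePointSet,
    cubature3_points,
    cubature5_points,
    sqrt_factor,
    unscented_points,
)

__all__ = [
    "GaussianBelief",
    "MeasurementModel",
    "FilterStepRecord",
    "FilterConfig",
    "FilterDivergence",
    "predict",
    "update_linear",
    "update_general",
    "augmented_jacobian",
    "ekf_step",
    "run_filter",
    "make_rule",
]

logger = logging.getLogger(__name__)

FilterName = Literal["ekf", "ukf", "ckf3", "ckf5"]


class FilterDivergence(RuntimeError):
    """Raised when the filter covariance exceeds the divergence bound."""

    def __init__(self, step: int, norm: float):
        super().__init__(
            f"filter diverged at step {step}: covariance norm {norm:.3g}"
        )
        self.step = step
        self.norm = norm


@dataclass
class GaussianBelief:
    mean: NDArray[np.float64]
    cov: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError("covariance shape does not match mean")
        if np.abs(self.cov - self.cov.T).max() > 1e-9 * max(
            1.0, np.abs(self.cov).max()
        ):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class MeasurementModel:
    """Linear observation ``y = B xbar + noise``; here B selects the x-block."""

    B: NDArray[np.float64]
    R: NDArray[np.float64]

    @staticmethod
    def expression_levels(n: int, R: NDArray[np.float64]) -> "MeasurementModel":
        B = np.zeros((n, augmented_dim(n)))
        B[:, :n] = np.eye(n)
        return MeasurementModel(B=B, R=np.asarray(R, dtype=float))


@dataclass
class FilterStepRecord:
    k: int
    predicted: GaussianBelief
    filtered: GaussianBelief
    innovation: NDArray[np.float64]
    gain: NDArray[np.float64]


def _symmetrize(P: NDArray[np.float64]) -> NDArray[np.float64]:
    return 0.5 * (P + P.T)


def _repair_psd(P: NDArray[np.float64]) -> NDArray[np.float64]:
    """Project a symmetric matrix onto the PSD cone if needed.

    The unscented transform with kappa < 0 carries a negative origin
    weight, so a predicted covariance can acquire small negative
    eigenvalues; those are clipped to zero.  Matrices that already admit a
    Cholesky factor are returned unchanged.
    """
    P = _symmetrize(P)
    try:
        np.linalg.cholesky(P)
        return P
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(P)
        if w.min() < 0:
            logger.debug("clipping negative covariance eigenvalue %g", w.min())
        return _symmetrize((V * np.clip(w, 0.0, None)) @ V.T)


def predict(
    belief: GaussianBelief,
    dynamics: Callable[[NDArray[np.float64]], NDArray[np.float64]],
    Q: NDArray[np.float64],
    rule: QuadraturePointSet,
) -> GaussianBelief:
    """Quadrature prediction: propagate sigma points through ``dynamics``.

    ``dynamics`` must map an (N, d) array of points to (N, d) images.
    """
    if rule.dim != belief.dim:
        raise ValueError("rule dimension does not match belief")
    S = sqrt_factor(belief.cov).S
    xi = rule.points @ S.T + belief.mean
    fx = dynamics(xi)
    mean = rule.weights @ fx
    dev = fx - mean
    cov = (dev.T * rule.weights) @ dev + Q
    return GaussianBelief(mean=mean, cov=_repair_psd(cov))


def update_linear(
    predicted: GaussianBelief,
    y: NDArray[np.float64],
    model: MeasurementModel,
) -> FilterStepRecord:
    """Exact Kalman measurement update for the linear model ``y = B x``."""
    B, R = model.B, model.R
    y = np.asarray(y, dtype=float)
    PBt = predicted.cov @ B.T
    Syy = R + B @ PBt
    try:
        L = np.linalg.solve(Syy.T, PBt.T).T
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"innovation covariance not invertible: {e}"
        ) from e
    innov = y - B @ predicted.mean
    mean = predicted.mean + L @ innov
    cov = _repair_psd(predicted.cov - L @ PBt.T)
    return FilterStepRecord(
        k=-1,
        predicted=predicted,
        filtered=GaussianBelief(mean=mean, cov=cov),
        innovation=innov,
        gain=L,
    )


def update_general(
    predicted: GaussianBelief,
    y: NDArray[np.float64],
    h: Callable[[NDArray[np.float64]], NDArray[np.float64]],
    R: NDArray[np.float64],
    rule: QuadraturePointSet,
) -> FilterStepRecord:
    """Quadrature measurement update for a nonlinear observation map.

    Provided for observation models beyond the noisy-expression case; the
    linear path is preferred when applicable since it is exact.
    """
    y = np.asarray(y, dtype=float)
    S = sqrt_factor(predicted.cov).S
    xi = rule.points @ S.T + predicted.mean
    hx = np.asarray(h(xi), dtype=float)
    yhat = rule.weights @ hx
    dx = xi - predicted.mean
    dy = hx - yhat
    Pxy = (dx.T * rule.weights) @ dy
    Pyy = (dy.T * rule.weights) @ dy
    Syy = R + Pyy
    L = np.linalg.solve(Syy.T, Pxy.T).T
    innov = y - yhat
    mean = predicted.mean + L @ innov
    cov = _symmetrize(predicted.cov - L @ Syy @ L.T)
    return FilterStepRecord(
        k=-1,
        predicted=predicted,
        filtered=GaussianBelief(mean=mean, cov=cov),
        innovation=innov,
        gain=L,
    )


def augmented_jacobian(xbar: NDArray[np.float64], n: int) -> NDArray[np.float64]:
    """Jacobian of the augmented drift at ``xbar``.

    With g_i' = mu_i g_i (1 - g_i) and row-major coefficient layout:

    * d(Ag)/dx      = A diag(g')
    * d(Ag)_i/da_ij = g_j              (block I_n kron g^T)
    * d(Ag)_i/dmu_l = a_il x_l g_l (1 - g_l)
    * the parameter block is the identity.
    """
    xbar = np.asarray(xbar, dtype=float)
    d = augmented_dim(n)
    if xbar.shape != (d,):
        raise ValueError("xbar has wrong length")
    x = xbar[:n]
    A = xbar[n : n + n * n].reshape(n, n)
    mu = np.maximum(xbar[n + n * n :], 1e-12)
    g = sigmoid_activation(x, mu)
    gp_x = mu * g * (1.0 - g)   # dg/dx
    gp_mu = x * g * (1.0 - g)   # dg/dmu
    F = np.zeros((d, d))
    F[:n, :n] = A * gp_x
    for i in range(n):
        F[i, n + i * n : n + (i + 1) * n] = g
    F[:n, n + n * n :] = A * gp_mu
    F[n:, n:] = np.eye(n * n + n)
    return F


def ekf_step(
    belief: GaussianBelief,
    y: NDArray[np.float64],
    n: int,
    Q: NDArray[np.float64],
    model: MeasurementModel,
) -> FilterStepRecord:
    """First-order (extended Kalman) prediction followed by the linear update."""
    F = augmented_jacobian(belief.mean, n)
    mean = augmented_dynamics(belief.mean, n)
    cov = _symmetrize(F @ belief.cov @ F.T + Q)
    return update_linear(GaussianBelief(mean=mean, cov=cov), y, model)


def make_rule(name: FilterName, d: int, kappa: float | None = None) -> QuadraturePointSet | None:
    """Quadrature rule backing a named filter (None for the EKF)."""
    if name == "ekf":
        return None
    if name == "ukf":
        return unscented_points(d, kappa)
    if name == "ckf3":
        return cubature3_points(d)
    if name == "ckf5":
        return cubature5_points(d)
    raise ValueError(f"unknown filter {name!r}")


@dataclass
class FilterConfig:
    """Run configuration for :func:`run_filter`.

    ``a_init_mean/var`` and ``mu_init_mean/var`` give the Gaussian prior
    from which the coefficient and steepness estimates are initialized; the
    x-block is initialized from the first measurement, so filtering starts
    at the second time point.
    """

    filter: FilterName = "ukf"
    kappa: float | None = None          # UT only; default 3 - d
    noise: NoiseSpec | None = None      # Q, R assumed by the filter
    seed: int = 0                       # initialization draw
    theta_init: NDArray[np.float64] | None = None  # overrides the random draw
    a_init_mean: float = 0.0
    a_init_var: float = 0.2
    mu_init_mean: float = 1.5
    mu_init_var: float = 0.2
    penalty: "object | None" = None     # priors.PenaltySpec
    range_constraint: "object | None" = None  # priors.RangeConstraint
    ista_eps: float = 1e-6
    ista_max_iter: int = 500
    divergence_bound: float = 1e6
    keep_records: bool = True


def run_filter(
    measurements: NDArray[np.float64],
    config: FilterConfig,
) -> tuple[list[FilterStepRecord], GRNParameters]:
    """Run the configured filter over a genes-by-time measurement series.

    ``measurements`` is K x n (rows are time points).  Returns the per-step
    records (empty if ``keep_records`` is off) and the network parameters
    decoded from the final filtered mean.
    """
    from . import priors  # local import; priors builds on this module's types

    Y = np.asarray(measurements, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("measurements must be K x n with K >= 2")
    K, n = Y.shape
    if config.noise is None:
        raise ValueError("FilterConfig.noise must be set")
    noise = config.noise
    if noise.n != n:
        raise ValueError("noise dimension does not match measurements")
    d = augmented_dim(n)
    Q_aug = noise.q_augmented()
    model = MeasurementModel.expression_levels(n, noise.R)
    rule = make_rule(config.filter, d, config.kappa)

    if config.theta_init is not None:
        theta0 = np.asarray(config.theta_init, dtype=float)
        if theta0.shape != (n * n + n,):
            raise ValueError("theta_init must have length n^2 + n")
    else:
        rng = np.random.default_rng(config.seed)
        theta0 = np.concatenate(
            [
                rng.normal(config.a_init_mean, np.sqrt(config.a_init_var), size=n * n),
                rng.normal(config.mu_init_mean, np.sqrt(config.mu_init_var), size=n),
            ]
        )
    mean0 = np.concatenate([Y[0], theta0])
    cov0 = np.zeros((d, d))
    cov0[:n, :n] = noise.R
    np.fill_diagonal(cov0[n:, n:], np.concatenate(
        [np.full(n * n, config.a_init_var), np.full(n, config.mu_init_var)]
    ))
    belief = GaussianBelief(mean=mean0, cov=cov0)

    dynamics = lambda pts: augmented_dynamics(pts, n)  # noqa: E731
    records: list[FilterStepRecord] = []
    for k in range(1, K):
        if config.filter == "ekf":
            rec = ekf_step(belief, Y[k], n, Q_aug, model)
        else:
            predicted = predict(belief, dynamics, Q_aug, rule)
            rec = update_linear(predicted, Y[k], model)
        rec.k = k
        if config.penalty is not None:
            rec.filtered.mean = priors.iterative_thresholding_update(
                rec.predicted,
                Y[k],
                model,
                config.penalty,
                eps=config.ista_eps,
                max_iter=config.ista_max_iter,
            )
        if config.range_constraint is not None:
            rec.filtered = priors.apply_range_constraints(
                rec.filtered, config.range_constraint
            )
        norm = float(np.linalg.norm(rec.filtered.cov))
        if norm > config.divergence_bound:
            raise FilterDivergence(k, norm)
        belief = rec.filtered
        if config.keep_records:
            records.append(rec)

    params = decode_params(belief.mean[n:], n)
    return records, params
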