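"""Unit-Gaussian quadrature point sets for sigma-point filtering.

Three rules are provided, all approximating ``int h(x) N(x; 0, I) dx`` by
``sum_i w_i h(gamma_i)``:

* the unscented transform (2d+1 points, tunable kappa, degree-3 exact),
* the third-degree spherical-radial cubature rule (2d points),
* the fifth-degree cubature rule built from the vertices and edge midpoints
  of a regular d-simplex (Mysovskikh construction; d^2 + 3d + 3 points).

A general-covariance integral is handled by a square-root factor S of P
(Cholesky, with an SVD fallback for semidefinite P) via the substitution
``x = S gamma + mean``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "QuadraturePointSet",
    "SquareRootFactor",
    "unscented_points",
    "cubature3_points",
    "cubature5_points",
    "sqrt_factor",
    "gaussian_integral",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuadraturePointSet:
    points: NDArray[np.float64]   # N x d abscissas for the unit Gaussian
    weights: NDArray[np.float64]  # length-N, sums to 1
    degree: int                   # polynomial exactness degree
    kappa: float | None = None    # UT tuning parameter, if applicable

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("point/weight count mismatch")

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class SquareRootFactor:
    S: NDArray[np.float64]
    method: str  # "cholesky" | "svd"


def unscented_points(d: int, kappa: float | None = None) -> QuadraturePointSet:
    """Unscented transform: origin plus ±sqrt(d+kappa) e_i.

    The origin carries weight kappa/(d+kappa), the axis points
    1/(2(d+kappa)).  Default kappa = 3 - d (the classical choice matching
    the fourth moment of a scalar Gaussian); negative kappa gives a
    negative origin weight, which is admissible but logged.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    if kappa is None:
        kappa = 3.0 - d
    scale = d + kappa
    if scale <= 0:
        raise ValueError(f"d + kappa must be positive, got {scale}")
    if kappa < 0:
        logger.debug("unscented transform with kappa=%g has a negative origin weight", kappa)
    pts = np.zeros((2 * d + 1, d))
    r = np.sqrt(scale)
    pts[1 : d + 1] = r * np.eye(d)
    pts[d + 1 :] = -r * np.eye(d)
    w = np.full(2 * d + 1, 1.0 / (2.0 * scale))
    w[0] = kappa / scale
    return QuadraturePointSet(points=pts, weights=w, degree=3, kappa=float(kappa))


def cubature3_points(d: int) -> QuadraturePointSet:
    """Third-degree spherical-radial rule: ±sqrt(d) e_i, uniform weights."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    r = np.sqrt(d)
    pts = np.vstack([r * np.eye(d), -r * np.eye(d)])
    w = np.full(2 * d, 1.0 / (2.0 * d))
    return QuadraturePointSet(points=pts, weights=w, degree=3)


def _simplex_vertices(d: int) -> NDArray[np.float64]:
    """Vertices of a regular simplex on the unit sphere in R^d.

    Rows s^(i), i = 1..d+1, with unit norm and pairwise inner products
    -1/d.
    """
    n = d
    S = np.zeros((n + 1, n))
    for i in range(1, n + 2):       # vertex index, 1-based
        for j in range(1, n + 1):   # coordinate index, 1-based
            if j < i:
                S[i - 1, j - 1] = -np.sqrt(
                    (n + 1.0) / (n * (n - j + 2.0) * (n - j + 1.0))
                )
            elif j == i:
                S[i - 1, j - 1] = np.sqrt(
                    (n + 1.0) * (n - i + 1.0) / (n * (n - i + 2.0))
                )
    return S


def cubature5_points(d: int) -> QuadraturePointSet:
    """Fifth-degree cubature rule from the regular-simplex construction.

    Points: the origin; ±sqrt(d+2) times the d+1 simplex vertices; and
    ±sqrt(d+2) times the d(d+1)/2 normalized pairwise vertex midpoints.
    Total d^2 + 3d + 3 points.  For d >= 8 the vertex weight w1 turns
    negative (the rule remains degree-5 exact).

    Requires d >= 2; in one dimension the 3-point Gauss-Hermite rule is
    returned instead (it is the degree-5 rule there).
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    if d == 1:
        logger.debug("cubature5_points(d=1): using 3-point Gauss-Hermite")
        pts = np.array([[0.0], [np.sqrt(3.0)], [-np.sqrt(3.0)]])
        w = np.array([2.0 / 3.0, 1.0 / 6.0, 1.0 / 6.0])
        return QuadraturePointSet(points=pts, weights=w, degree=5)

    s1 = _simplex_vertices(d)                       # (d+1) x d
    pairs = [
        (s1[k] + s1[l]) for k in range(d + 1) for l in range(k + 1, d + 1)
    ]
    s2 = np.sqrt(d / (2.0 * (d - 1.0))) * np.asarray(pairs)  # unit norm

    r = np.sqrt(d + 2.0)
    pts = np.vstack([np.zeros((1, d)), r * s1, -r * s1, r * s2, -r * s2])

    w0 = 2.0 / (d + 2.0)
    w1 = d**2 * (7.0 - d) / (2.0 * (d + 1.0) ** 2 * (d + 2.0) ** 2)
    w2 = 2.0 * (d - 1.0) ** 2 / ((d + 1.0) ** 2 * (d + 2.0) ** 2)
    w = np.concatenate(
        [
            [w0],
            np.full(2 * (d + 1), w1),
            np.full(d * (d + 1), w2),
        ]
    )
    return QuadraturePointSet(points=pts, weights=w, degree=5)


def sqrt_factor(P: NDArray[np.float64], tolerance: float = 1e-9) -> SquareRootFactor:
    """Square-root factor S with S S^T = P.

    Cholesky is attempted first (with a small diagonal jitter retry);
    positive-semidefinite matrices fall back to a symmetric eigenvalue
    factor.  Raises if P has an eigenvalue below ``-tolerance`` relative
    to its scale.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    scale = max(np.abs(P).max(), 1.0)
    if np.abs(P - P.T).max() > tolerance * scale:
        raise ValueError("P must be symmetric")
    Psym = 0.5 * (P + P.T)
    try:
        return SquareRootFactor(S=np.linalg.cholesky(Psym), method="cholesky")
    except np.linalg.LinAlgError:
        pass
    d = P.shape[0]
    jitter = 1e-10 * max(np.trace(Psym), 0.0) / d
    if jitter > 0:
        try:
            S = np.linalg.cholesky(Psym + jitter * np.eye(d))
            return SquareRootFactor(S=S, method="cholesky")
        except np.linalg.LinAlgError:
            pass
    w, V = np.linalg.eigh(Psym)
    if w.min() < -tolerance * scale:
        raise ValueError(f"P is not positive semidefinite (min eigenvalue {w.min():g})")
    return SquareRootFactor(S=V * np.sqrt(np.clip(w, 0.0, None)), method="svd")


def gaussian_integral(
    h: Callable[[NDArray[np.float64]], NDArray[np.float64]],
    mean: NDArray[np.float64],
    cov: NDArray[np.float64],
    rule: QuadraturePointSet,
) -> NDArray[np.float64]:
    """Approximate ``E[h(X)]`` for ``X ~ N(mean, cov)`` with the rule.

    ``h`` must accept an (N, d) array of points and return (N, ...) values.
    """
    mean = np.asarray(mean, dtype=float)
    if rule.dim != mean.shape[0]:
        raise ValueError("rule dimension does not match mean")
    S = sqrt_factor(cov).S
    xi = rule.points @ S.T + mean
    vals = np.asarray(h(xi), dtype=float)
    return np.tensordot(rule.weights, vals, axes=(0, 0))
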