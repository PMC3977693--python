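"""Sigmoid state-space model of a gene regulatory network.

A network of ``n`` genes evolves as

    x_k = A g(x_{k-1}) + v_k,        v_k ~ N(0, Q)
    y_k = x_k + n_k,                 n_k ~ N(0, R)

where ``x_k`` holds the expression levels, ``A`` is the signed regulatory
coefficient matrix (``a_ij`` = effect of gene ``j`` on gene ``i``; positive
= activation, negative = repression) and ``g`` applies the sigmoid
``g_i(x) = 1 / (1 + exp(-mu_i x))`` componentwise.  The sigmoid captures
saturation of transcriptional response.

For joint state-parameter inference the unknowns ``A`` and ``mu`` are
stacked into an augmented state ``xbar = [x; vec(A) (row-major); mu]`` of
dimension ``n^2 + 2n``; the parameter block follows random-walk dynamics
with zero process noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "GRNParameters",
    "NoiseSpec",
    "TrajectoryBundle",
    "sigmoid_activation",
    "propagate_state",
    "augmented_dim",
    "encode_params",
    "decode_params",
    "split_augmented",
    "augmented_dynamics",
    "simulate_trajectory",
    "fixture_network",
    "fixture_indicator",
]


@dataclass(frozen=True)
class GRNParameters:
    """Regulatory coefficient matrix ``A`` and sigmoid steepness ``mu``."""

    A: NDArray[np.float64]
    mu: NDArray[np.float64]

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        if mu.shape != (A.shape[0],):
            raise ValueError(
                f"mu must have length {A.shape[0]}, got shape {mu.shape}"
            )
        if not np.all(mu > 0):
            raise ValueError("sigmoid steepness mu must be strictly positive")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "mu", mu)

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class NoiseSpec:
    """State noise Q, measurement noise R and the augmented Q.

    ``Q_aug`` is block-diagonal ``diag[Q, 0]``: the parameter block is a
    random walk with exactly zero process noise.
    """

    Q: NDArray[np.float64]
    R: NDArray[np.float64]

    def __post_init__(self) -> None:
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        for name, M in (("Q", Q), ("R", R)):
            if M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(M, M.T, atol=1e-9):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-9 * max(1.0, np.trace(M)):
                raise ValueError(f"{name} must be positive semidefinite")
        if Q.shape != R.shape:
            raise ValueError("Q and R must both be n x n")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "R", R)

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def q_augmented(self) -> NDArray[np.float64]:
        """``diag[Q, O_{n^2+n}]`` on the augmented state."""
        n = self.n
        d = augmented_dim(n)
        Qa = np.zeros((d, d))
        Qa[:n, :n] = self.Q
        return Qa


@dataclass(frozen=True)
class TrajectoryBundle:
    """One simulated realization: true states, noisy measurements, truth."""

    states: NDArray[np.float64]
    measurements: NDArray[np.float64]
    params: GRNParameters
    seed: int

    def __post_init__(self) -> None:
        if self.states.shape != self.measurements.shape:
            raise ValueError("states and measurements must have equal shape")


def sigmoid_activation(x, mu):
    """Sigmoid ``1 / (1 + exp(-mu * x))``, elementwise.

    Strictly increasing in ``x`` with range (0, 1); ``mu`` controls the
    steepness at the origin.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("sigmoid steepness mu must be strictly positive")
    z = np.multiply(mu, x, dtype=float)
    # evaluate on the side that cannot overflow
    out = np.empty_like(np.atleast_1d(z), dtype=float)
    z1 = np.atleast_1d(z)
    pos = z1 >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z1[pos]))
    ez = np.exp(z1[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.reshape(np.shape(z)) if np.ndim(z) else float(out[0])


def propagate_state(x, params: GRNParameters):
    """One noise-free step of the dynamics: ``A g(x)``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n:
        raise ValueError(
            f"state length {x.shape[-1]} does not match n={params.n}"
        )
    return sigmoid_activation(x, params.mu) @ params.A.T


def augmented_dim(n: int) -> int:
    """Dimension of the augmented state: n expression levels + n^2
    coefficients + n steepness parameters."""
    return n * n + 2 * n


def encode_params(params: GRNParameters) -> NDArray[np.float64]:
    """Parameter block theta = [a11, a12, ..., ann, mu1, ..., mun]."""
    return np.concatenate([params.A.ravel(order="C"), params.mu])


def decode_params(theta: NDArray[np.float64], n: int) -> GRNParameters:
    """Inverse of :func:`encode_params`.

    The decoded ``mu`` is clipped below at a tiny positive floor so that a
    filter estimate that wanders nonpositive still yields a valid model.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n * n + n,):
        raise ValueError(f"theta must have length {n * n + n}")
    A = theta[: n * n].reshape(n, n)
    mu = np.maximum(theta[n * n :], 1e-12)
    return GRNParameters(A=A, mu=mu)


def split_augmented(xbar: NDArray[np.float64], n: int):
    """Split ``xbar`` into (x, theta) blocks."""
    xbar = np.asarray(xbar, dtype=float)
    if xbar.shape[-1] != augmented_dim(n):
        raise ValueError(
            f"augmented state must have length {augmented_dim(n)}"
        )
    return xbar[..., :n], xbar[..., n:]


def augmented_dynamics(xbar: NDArray[np.float64], n: int) -> NDArray[np.float64]:
    """Drift of the augmented model: propagate x, copy theta.

    Vectorized over leading axes so a whole sigma-point set can be pushed
    through in one call.
    """
    xbar = np.asarray(xbar, dtype=float)
    x, theta = split_augmented(xbar, n)
    A = theta[..., : n * n].reshape(*theta.shape[:-1], n, n)
    mu = np.maximum(theta[..., n * n :], 1e-12)
    g = sigmoid_activation(x, mu)
    x_next = np.einsum("...ij,...j->...i", A, g)
    out = np.concatenate([x_next, theta], axis=-1)
    return out


def simulate_trajectory(
    params: GRNParameters,
    noise: NoiseSpec,
    K: int,
    x0: NDArray[np.float64] | None = None,
    seed: int = 0,
) -> TrajectoryBundle:
    """Simulate ``K`` time points of expression data.

    ``x_k = A g(x_{k-1}) + v_k`` and ``y_k = x_k + n_k`` for k = 1..K.
    ``x0`` defaults to an i.i.d. standard-normal draw.  Deterministic
    given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    n = params.n
    if noise.n != n:
        raise ValueError("noise dimension does not match network size")
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = rng.standard_normal(n)
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (n,):
            raise ValueError(f"x0 must have length {n}")

    # draw through Cholesky-like factors; exact zeros give exact zero noise
    sq = _psd_sqrt(noise.Q)
    sr = _psd_sqrt(noise.R)
    states = np.empty((K, n))
    meas = np.empty((K, n))
    x = x0
    for k in range(K):
        x = propagate_state(x, params) + sq @ rng.standard_normal(n)
        states[k] = x
        meas[k] = x + sr @ rng.standard_normal(n)
    return TrajectoryBundle(states=states, measurements=meas, params=params, seed=seed)


def _psd_sqrt(M: NDArray[np.float64]) -> NDArray[np.float64]:
    w, V = np.linalg.eigh(np.asarray(M, dtype=float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w) @ V.T


# ---------------------------------------------------------------------------
# Eight-gene benchmark network.
#
# The printed source for this matrix is a run-on digit string; the parse
# below assigns eight entries per row and consumes the string exactly.  Two
# spots are typographically ambiguous and are fixed as documented:
#   * row 5, columns 7-8: "-14-1.5" read as (-1.4, -1.5), not (-14, -1.5);
#   * row 8 prints only seven values; a trailing 0 completes the row.
# The resulting matrix has 32 nonzero links (diagonal self-regulation
# included).
_FIXTURE_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.4, 3.2],     # 0000002.43.2
        [0.0, 0.0, 0.0, 4.1, 0.0, -2.4, 0.0, 4.1],    # 0004.10-2.404.1
        [-5.0, 2.1, -1.5, 0.0, 4.5, 0.0, 2.1, 0.0],   # -5.02.1-1.504.502.10
        [0.0, 1.3, 2.5, -3.7, 1.8, 0.0, 0.0, -3.1],   # 01.32.5-3.71.800-3.1
        [0.0, 0.0, 0.0, -2.6, -3.2, 0.0, -1.4, -1.5], # 000-2.6-3.20-14-1.5
        [-1.8, 0.0, 3.4, 1.4, 1.1, 0.0, 1.7, -1.8],   # -1.803.41.41.101.7-1.8
        [0.0, 0.0, -3.0, 1.1, 2.4, 0.0, 0.0, -1.3],   # 00-31.12.400-1.3
        [0.0, -1.0, 0.0, 2.1, 0.0, 0.0, 2.2, 0.0],    # 0-102.1002.2 (+ pad 0)
    ]
)


def fixture_network() -> GRNParameters:
    """The canonical eight-gene synthetic benchmark network (mu_i = 2)."""
    return GRNParameters(A=_FIXTURE_A.copy(), mu=np.full(8, 2.0))


def random_sparse_network(
    n: int,
    magnitude: float = 2.0,
    density: float = 0.5,
    mu: float = 2.0,
    seed: int = 0,
) -> GRNParameters:
    """Random sparse signed network for recovery studies.

    Each coefficient is ``+magnitude`` or ``-magnitude`` with probability
    ``density/2`` each, zero otherwise; at least one edge is guaranteed.
    The default density matches the eight-gene benchmark network (half of
    the 64 entries are links).
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    A = rng.choice(
        [0.0, magnitude, -magnitude],
        size=(n, n),
        p=[1.0 - density, density / 2.0, density / 2.0],
    )
    if not np.any(A):
        i = rng.integers(n)
        A[i, (i + 1) % n] = magnitude
    return GRNParameters(A=A, mu=np.full(n, mu))


def fixture_indicator() -> NDArray[np.float64]:
    """Prior-knowledge indicator matrix for the benchmark network.

    ``e_ij = 1`` marks a pair believed NOT to interact: genes 1, 5, 7 are
    unlikely to regulate gene 2, and genes 2, 3, 8 unlikely to regulate
    gene 7 (1-based gene labels).
    """
    E = np.zeros((8, 8))
    E[1, [0, 4, 6]] = 1.0
    E[6, [1, 2, 7]] = 1.0
    return E
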