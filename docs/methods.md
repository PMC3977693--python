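# Methods

## Model

Gene expression levels `x_k ∈ R^n` evolve in discrete time as

    x_k = A g(x_{k-1}) + v_k,        v_k ~ N(0, Q)
    y_k = x_k + n_k,                 n_k ~ N(0, R)

with `g_i(x) = 1 / (1 + exp(-μ_i x))` applied componentwise.  `A` is the
signed regulatory coefficient matrix — `a_ij > 0` means gene *j* activates
gene *i*, `a_ij < 0` repression — and `μ_i > 0` sets the steepness of the
transcriptional response.  The sigmoid encodes saturation: no matter how
strongly a regulator is expressed, its contribution to a target is bounded
by `|a_ij|`.

Inference is joint state–parameter estimation by state augmentation: the
filter state is `x̄ = [x; a_11, …, a_nn (row-major); μ_1, …, μ_n]` of
dimension `n² + 2n` (80 for the eight-gene benchmark).  The parameter
block follows a random walk with exactly zero process noise, so the
augmented process covariance is `diag[Q, 0]`.  Because measurements are
noisy expression levels, the observation map is linear
(`B = [I_n, 0]`) and the measurement update is the exact Kalman update;
all nonlinearity sits in the prediction step.

## Filters

Prediction propagates the Gaussian belief through the dynamics with a
quadrature rule for unit-Gaussian expectations, `E[h(X)] ≈ Σ w_i h(Sγ_i +
x̂)` with `S Sᵀ = P`:

* **UT (UKF)** — `2d+1` points at the origin and `±√(d+κ) e_i`; κ is
  tunable, default `3 − d`.  The benchmark arms use `κ = 3 − n` with *n*
  the gene count (κ = −5 at n = 8), the convention of the reference study
  this package reproduces.
* **CKF3** — `2d` points `±√d e_i`, uniform weights; identical to the UT
  with κ = 0 (minus the zero-weight origin).
* **CKF5** — the fifth-degree spherical–radial rule built from a regular
  d-simplex (Mysovskikh construction): origin, the `d+1` vertices and the
  `d(d+1)/2` normalized edge midpoints, each mirrored; `d² + 3d + 3`
  points.  The origin weight `2/(d+2)` is the unique value normalizing
  the weights.  For `d ≥ 8` the vertex weight `d²(7−d)/(2(d+1)²(d+2)²)`
  is negative; the rule stays degree-5 exact.  In one dimension the
  construction is empty and the 3-point Gauss–Hermite rule (degree-5
  exact there) is substituted.
* **EKF baseline** — first-order linearization with the analytic Jacobian
  of the augmented drift (`∂g/∂x = μ g(1−g)`, `∂g/∂μ = x g(1−g)`,
  coefficients enter linearly through `g`).

Numerical choices.  Covariances are symmetrized after every step.  With
negative quadrature weights (any κ < 0, and CKF5 at d ≥ 8) a predicted
covariance can acquire small negative eigenvalues; whenever a Cholesky
factorization fails, the matrix is projected onto the PSD cone by
clipping negative eigenvalues to zero.  Square-root factors prefer
Cholesky (with one jittered retry, `1e-10·tr(P)/d`), falling back to a
symmetric-eigendecomposition factor for semidefinite matrices.  A
divergence guard aborts a run if the covariance Frobenius norm exceeds
`1e6`.  Inside the filter the steepness block of a sigma point is floored
at `1e-12` before evaluating the sigmoid, keeping every point a valid
model; estimates essentially never reach that floor in practice.

Initialization follows the benchmark protocol: coefficients drawn from
N(0, 0.2), steepness from N(1.5, 0.2), the expression block set to the
first measurement (which is therefore consumed; filtering starts at the
second time point).  The initial covariance — not fixed by the protocol —
is taken as `diag[R, 0.2 I_{n²}, 0.2 I_n]`, making the random
initialization coherent as a Gaussian prior.

## Prior knowledge

**L1-penalized updates.**  The Kalman filtered mean minimizes
`J(x̄) = (y − Bx̄)ᵀR⁻¹(y − Bx̄) + (x̄ − x̂)ᵀP⁻¹(x̄ − x̂)`.  Sparsity and
known-non-edge priors add `‖λ ∘ x̄‖₁` with per-component weights that are
zero outside the coefficient block: a uniform weight λ on all n²
coefficients (LASSO), or `λ·e_ij` with an indicator/strength matrix E
whose positive entries mark pairs believed *not* to interact.  The
penalized minimizer is found by iterative soft thresholding: gradient
step of size 1/α, shrinkage by λ/α, with α from the Barzilai–Borwein
formula `(sᵀr)/‖s‖²` clamped to `[1e-8, 1e8]`.  The iteration warm-starts
at the unpenalized Kalman mean with α from the mean Hessian diagonal
`tr(2(BᵀR⁻¹B + P⁻¹))/d`, and is safeguarded by doubling α (shrinking the
step) until the penalized objective does not increase — the plain BB
iteration can oscillate.  Stopping: relative objective change below
`1e-6`, at most 500 iterations.  Inverses are never formed; both
quadratic terms go through Cholesky solves, with the same jitter policy
as above.  Only the filtered *mean* is replaced by the penalized
solution; the filtered covariance is kept from the standard update, since
the penalized problem defines no covariance.

**Range constraints.**  Componentwise bounds `c ≤ x̄ ≤ d` are imposed by
sequential PDF truncation (ascending component order; the result is
mildly order-dependent).  For each finite bound the covariance is
eigendecomposed, an orthogonal transform (a Householder completion of the
required first row) rotates the constrained direction into the first
coordinate, that coordinate's standard-normal density is truncated to the
normalized interval and replaced by its truncated-normal mean and
variance (computed with `scipy.stats.truncnorm`), and the transform is
inverted.  Bounds farther than 8.5 standard deviations on both sides are
skipped — the truncated moments equal (0, 1) to machine precision there —
which makes loose ±10 bounds essentially free.  The truncated variance
never exceeds 1, so the constrained direction's variance never grows.
In the benchmark, bounds are applied to the coefficient block only
(±0.1 on prior-flagged entries, ±10 elsewhere); expression levels and
steepness stay unbounded.

## Synthetic benchmark

The generator reproduces the eight-gene study conditions: the fixed 8×8
coefficient matrix (32 signed links, diagonal self-regulation included),
μ_i = 2, 40 time points, `Q = 0.01 I₈` on the expression block,
`R = 0.01 I₈`, initial state drawn i.i.d. standard normal (the protocol
does not fix it; the dynamics have a single global attractor — a noisy
limit cycle — so the choice is immaterial after a short transient).  The
printed source of the coefficient matrix is a run-on digit string with
two typographic ambiguities; the parse is documented entry-by-entry in
`model.py` and flagged to users.  Monte-Carlo runs use seed
`base_seed + i` for the trajectory and an offset stream for the filter
initialization; all filter arms of a run share the same trajectory
(paired design).

**Scoring.**  An estimate is reduced to links by `|â_ij| > τ`, scored
over all n² entries.  Scoring is sign-aware: a called link on a true edge
counts as a true positive only when its sign matches; with the wrong sign
it is a false positive (an incorrect interaction was asserted).  Boolean
inputs to `evaluate` give plain sign-blind scoring.  TPR, FPR and PPV are
averaged per run (mean of per-run metrics, not metrics of mean counts).

**Threshold calibration.**  τ is the benchmark's one free decision
parameter.  The packaged default (τ = 0.25) is calibrated by matching the
plain UKF's average FPR to the reference operating point FPR 0.5955 — the
standard ROC practice of comparing detectors at equal specificity — on a
50-run benchmark with base seed 0; `calibrate_tau` re-derives it for any
seed, and the CLI exposes `--tau` directly.

**What the synthetic benchmark does and does not show.**  It exercises
exactly the generating model the filter assumes (matched noise
covariances, known model class, time-invariant A), with strong persistent
excitation from the limit cycle.  Real expression data adds model
mismatch, unlogged measurement distortions, slow sampling and far fewer
time points, so passing numbers here bound the method's behavior only
under ideal conditions.  Notably, a numerically careful implementation of
these filters recovers substantially more of the network on this
benchmark than the historically reported figures for the same protocol
(average sign-aware TPR ≈ 0.95 at FPR ≈ 0.60 for the plain UKF, and an
EKF nearly as good as the sigma-point filters): an independent
Bayesian-ridge cross-check (regressing `y_k` on `g(y_{k-1})`) confirms
the data genuinely supports that accuracy, placing the historical
operating points well inside the achievable ROC.  Differences between
filters at matched specificity are correspondingly compressed on this
benchmark.

**Small-network recovery study.**  `random_sparse_network` draws 3-gene
networks with entries ±2 at density 0.5 (matching the eight-gene
network's link density).  Some draws settle into a fixed point where the
sigmoid regressors are constant up to noise; coefficients are then
unidentifiable and their estimates remain near the random initialization.
Sign-recovery rates across seeds should be read with that in mind.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| κ (UT) | 3 − d (3 − n in the benchmark) | sigma-point spread/weights |
| λ | 1 (LASSO and indicator) | L1 penalty strength; larger = sparser |
| τ | 0.25 | link-calling threshold on |â_ij| |
| Q, R | 0.01 I | process / measurement noise (unitless expression scale) |
| ε, max_iter | 1e-6, 500 | thresholding stopping rule |
| divergence bound | 1e6 | covariance norm abort threshold |

## Known limitations

- Computational cost grows as d²–d³ per step with d = n² + 2n; intended
  for small and medium networks (up to a few dozen genes).
- No smoothing, adaptive noise estimation, or square-root filter forms.
- Sequential PDF truncation is order-dependent; ascending component order
  is fixed and documented.
- The penalized update has no covariance theory; the standard-update
  covariance is reused unchanged.
- Time-varying regulation, missing data, and non-Gaussian noise are out
  of scope.
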