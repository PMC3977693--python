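"""End-to-end inference pipeline and Monte-Carlo benchmark harness.

:func:`infer_network` runs one filter over one expression series and calls
links; :func:`monte_carlo_benchmark` repeats simulate-infer-evaluate over
seeded runs for a set of filter conditions and aggregates min/max/avg per
metric, the layout used throughout the synthetic eight-gene benchmark.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .evaluate import ConfusionCounts, EvaluationMetrics, call_links, evaluate, signed_links
from .filters import FilterConfig, FilterDivergence, FilterStepRecord, run_filter
from .model import (
    GRNParameters,
    NoiseSpec,
    fixture_network,
    simulate_trajectory,
)
from .priors import PenaltySpec, RangeConstraint

__all__ = [
    "DEFAULT_TAU",
    "Condition",
    "BenchmarkSummary",
    "infer_network",
    "monte_carlo_benchmark",
    "benchmark_conditions",
    "calibrate_tau",
]

logger = logging.getLogger(__name__)

#: Default link-calling threshold on |a_ij|.  The decision rule behind the
#: reported link counts is not part of the generating model, so the default
#: is calibrated (see :func:`calibrate_tau`) to place the plain UKF's
#: average FPR on the eight-gene benchmark at the reference operating
#: point (FPR 0.5955); sensitivities are then comparable at matched
#: specificity.
DEFAULT_TAU = 0.25

# offset separating the filter-initialization stream from the simulation
# stream of the same run
_INIT_SEED_OFFSET = 1_000_003


@dataclass(frozen=True)
class Condition:
    """One benchmark arm: a filter plus an optional prior-knowledge mode."""

    label: str
    filter: str = "ukf"
    kappa: float | None = None
    penalty: PenaltySpec | None = None
    range_constraint: RangeConstraint | None = None


@dataclass
class BenchmarkSummary:
    """Per-run rows plus min/max/avg aggregates of a Monte-Carlo benchmark.

    The raw coefficient estimates are kept per (condition, run) so the
    link threshold can be swept without re-running any filter.
    """

    rows: pd.DataFrame
    runs: int
    base_seed: int
    tau: float
    truth: NDArray[np.float64] | None = None
    estimates: dict[str, list[tuple[int, NDArray[np.float64]]]] = field(
        default_factory=dict
    )
    diverged: list[tuple[str, int]] = field(default_factory=list)

    def rescore(self, tau: float) -> "BenchmarkSummary":
        """Re-call links at a different threshold from stored estimates."""
        if self.truth is None or not self.estimates:
            raise ValueError("summary carries no stored estimates")
        rows = _score_rows(self.estimates, self.truth, tau, self.base_seed)
        return BenchmarkSummary(
            rows=rows, runs=self.runs, base_seed=self.base_seed, tau=tau,
            truth=self.truth, estimates=self.estimates, diverged=self.diverged,
        )

    def aggregates(self) -> pd.DataFrame:
        """min/max/avg of each metric per condition (long format)."""
        out = []
        for label, grp in self.rows.groupby("condition", sort=False):
            for metric in ("tp", "fp", "tn", "fn", "tpr", "fpr", "ppv"):
                vals = grp[metric].to_numpy(dtype=float)
                out.append(
                    {
                        "condition": label,
                        "metric": metric,
                        "min": np.nanmin(vals),
                        "max": np.nanmax(vals),
                        "avg": np.nanmean(vals),
                    }
                )
        return pd.DataFrame(out)

    def avg(self, condition: str, metric: str) -> float:
        grp = self.rows[self.rows["condition"] == condition]
        if grp.empty:
            raise KeyError(f"no condition {condition!r} in benchmark")
        return float(np.nanmean(grp[metric].to_numpy(dtype=float)))


def infer_network(
    measurements: NDArray[np.float64],
    config: FilterConfig,
    tau: float = DEFAULT_TAU,
) -> tuple[GRNParameters, NDArray[np.bool_], list[FilterStepRecord]]:
    """Run one filter over a K x n series and call links on the estimate."""
    records, params = run_filter(measurements, config)
    adjacency = call_links(params.A, tau)
    return params, adjacency, records


def benchmark_conditions(
    n: int,
    filters: list[str] | None = None,
    lasso_lambda: float | None = None,
    indicator: NDArray[np.float64] | None = None,
    indicator_lambda: float = 1.0,
    range_tight_mask: NDArray[np.bool_] | None = None,
    range_tight: float = 0.1,
    range_loose: float = 10.0,
) -> list[Condition]:
    """Assemble benchmark arms from simple switches.

    ``filters`` lists unconstrained arms; a LASSO arm, an indicator-prior
    arm and a range-constrained arm (each on the UKF) are appended when
    their inputs are given.
    """
    # the benchmark's "ukf" arm uses kappa = 3 - n with n the gene count
    conds = [
        Condition(
            label=f, filter=f, kappa=(3.0 - n if f == "ukf" else None)
        )
        for f in (filters or ["ukf"])
    ]
    if lasso_lambda is not None:
        conds.append(
            Condition(
                label=f"ukf_lasso(lam={lasso_lambda:g})",
                kappa=3.0 - n,
                penalty=PenaltySpec.lasso(n, lasso_lambda),
            )
        )
    if indicator is not None:
        conds.append(
            Condition(
                label=f"ukf_indicator(lam={indicator_lambda:g})",
                kappa=3.0 - n,
                penalty=PenaltySpec.indicator(indicator, indicator_lambda),
            )
        )
    if range_tight_mask is not None:
        conds.append(
            Condition(
                label="ukf_range",
                kappa=3.0 - n,
                range_constraint=RangeConstraint.on_coefficients(
                    n,
                    tight_mask=range_tight_mask,
                    tight=range_tight,
                    loose=range_loose,
                ),
            )
        )
    return conds


def monte_carlo_benchmark(
    conditions: list[Condition],
    params: GRNParameters | None = None,
    noise: NoiseSpec | None = None,
    K: int = 40,
    runs: int = 50,
    tau: float = DEFAULT_TAU,
    base_seed: int = 0,
    filter_defaults: FilterConfig | None = None,
) -> BenchmarkSummary:
    """Seeded simulate-infer-evaluate loop over all conditions.

    Run ``i`` simulates one trajectory with seed ``base_seed + i`` shared
    by every condition (paired design), infers with each condition's
    filter, thresholds at ``tau`` and scores against the true adjacency.
    Diverged runs are recorded and excluded from the aggregates.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if params is None:
        params = fixture_network()
    n = params.n
    if noise is None:
        noise = NoiseSpec(Q=0.01 * np.eye(n), R=0.01 * np.eye(n))
    base = filter_defaults or FilterConfig()

    estimates: dict[str, list] = {c.label: [] for c in conditions}
    diverged: list[tuple[str, int]] = []
    for i in range(runs):
        sim_seed = base_seed + i
        bundle = simulate_trajectory(params, noise, K=K, seed=sim_seed)
        for cond in conditions:
            cfg = dataclasses.replace(
                base,
                filter=cond.filter,
                kappa=cond.kappa,
                noise=noise,
                penalty=cond.penalty,
                range_constraint=cond.range_constraint,
                seed=_INIT_SEED_OFFSET + base_seed + i,
                keep_records=False,
            )
            try:
                _, est = run_filter(bundle.measurements, cfg)
            except FilterDivergence as e:
                logger.warning(
                    "run %d condition %s diverged: %s", i, cond.label, e
                )
                diverged.append((cond.label, i))
                continue
            estimates[cond.label].append((i, est.A))
    rows = _score_rows(estimates, params.A, tau, base_seed)
    if diverged:
        logger.warning("%d diverged runs excluded from aggregates", len(diverged))
    return BenchmarkSummary(
        rows=rows,
        runs=runs,
        base_seed=base_seed,
        tau=tau,
        truth=params.A.copy(),
        estimates=estimates,
        diverged=diverged,
    )


def _score_rows(
    estimates: dict[str, list[tuple[int, NDArray[np.float64]]]],
    truth_A: NDArray[np.float64],
    tau: float,
    base_seed: int,
) -> pd.DataFrame:
    """Sign-aware scoring of stored estimates at threshold ``tau``."""
    truth_signed = np.sign(truth_A).astype(int)
    rows = []
    for label, runs in estimates.items():
        for i, A_hat in runs:
            counts, metrics = evaluate(signed_links(A_hat, tau), truth_signed)
            rows.append(
                {
                    "condition": label,
                    "run": i,
                    "seed": base_seed + i,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "tn": counts.tn,
                    "fn": counts.fn,
                    "tpr": metrics.tpr,
                    "fpr": metrics.fpr,
                    "ppv": metrics.ppv,
                }
            )
    return pd.DataFrame(rows)


def calibrate_tau(
    summary: BenchmarkSummary,
    target_fpr: float,
    condition: str = "ukf",
    grid: NDArray[np.float64] | None = None,
) -> float:
    """Link threshold matching a reference false positive rate.

    Sweeps ``tau`` over ``grid`` (default 0.02..1.50 step 0.01) and picks
    the value whose average FPR on ``condition`` is closest to
    ``target_fpr``.  Matching the false-positive operating point is the
    standard way to compare detectors along a ROC curve; sensitivity
    comparisons are then made at the same specificity.
    """
    if grid is None:
        grid = np.arange(0.02, 1.5001, 0.01)
    best_tau, best_err = float(grid[0]), np.inf
    for tau in grid:
        fpr = summary.rescore(float(tau)).avg(condition, "fpr")
        err = abs(fpr - target_fpr)
        if err < best_err:
            best_tau, best_err = float(tau), err
    return best_tau
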