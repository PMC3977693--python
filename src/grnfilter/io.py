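"""Delimited-text input/output for expression data, networks and priors.

All formats are plain TSV (CSV accepted on read):

* expression matrix: genes as rows, time points as columns, header
  ``gene<TAB>t1...tK``;
* network: dense n x n matrix, or a signed edge list
  ``source<TAB>target<TAB>weight``;
* adjacency: dense 0/1 matrix;
* indicator/strength prior: dense nonnegative n x n matrix;
* bounds: rows ``component<TAB>lower<TAB>upper`` with components named
  ``x_i``, ``a_i_j`` or ``mu_i`` (1-based); missing components are
  unbounded;
* benchmark report: ``condition<TAB>metric<TAB>min<TAB>max<TAB>avg``
  plus a JSON twin.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .model import augmented_dim
from .pipeline import BenchmarkSummary
from .priors import RangeConstraint

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_network",
    "write_network",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "read_indicator",
    "read_bounds",
    "write_benchmark_report",
    "write_step_trace",
]


class ParseError(ValueError):
    pass


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(path: str | Path) -> tuple[NDArray[np.float64], list[str]]:
    """Read a genes-by-time table; returns (K x n matrix, gene names)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    bad = df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: missing or non-numeric value at gene {df.index[r]!r},"
            f" column {df.columns[c]!r} (data row {r + 1})"
        )
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric entry ({e})") from e
    return mat.T.copy(), [str(g) for g in df.index]


def write_expression_matrix(
    path: str | Path,
    measurements: NDArray[np.float64],
    gene_names: list[str] | None = None,
) -> None:
    """Write a K x n series as a genes-by-time table."""
    Y = np.asarray(measurements, dtype=float)
    K, n = Y.shape
    names = gene_names or [f"gene{i + 1}" for i in range(n)]
    df = pd.DataFrame(
        Y.T, index=pd.Index(names, name="gene"),
        columns=[f"t{k + 1}" for k in range(K)],
    )
    df.to_csv(path, sep=_sep(path))


def read_network(path: str | Path) -> NDArray[np.float64]:
    """Read a dense n x n coefficient matrix (no header)."""
    try:
        A = np.loadtxt(path, delimiter=_sep(path), ndmin=2)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e
    if A.shape[0] != A.shape[1]:
        raise ParseError(f"{path}: matrix is {A.shape[0]}x{A.shape[1]}, not square")
    return A


def write_network(path: str | Path, A: NDArray[np.float64]) -> None:
    np.savetxt(path, np.asarray(A, dtype=float), delimiter="\t", fmt="%.10g")


def write_edge_list(path: str | Path, A: NDArray[np.float64], tau: float = 0.0) -> None:
    """Signed edge list (source, target, weight) of entries with |a| > tau."""
    A = np.asarray(A, dtype=float)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i in range(A.shape[0]):
            for j in range(A.shape[1]):
                if abs(A[i, j]) > tau:
                    fh.write(f"gene{j + 1}\tgene{i + 1}\t{A[i, j]:.10g}\n")


def read_adjacency(path: str | Path) -> NDArray[np.bool_]:
    return read_network(path) != 0


def write_adjacency(path: str | Path, adjacency: NDArray[np.bool_]) -> None:
    np.savetxt(
        path, np.asarray(adjacency, dtype=int), delimiter="\t", fmt="%d"
    )


def read_indicator(path: str | Path) -> NDArray[np.float64]:
    """Nonnegative indicator/strength prior matrix."""
    E = read_network(path)
    if np.any(E < 0):
        raise ParseError(f"{path}: indicator entries must be nonnegative")
    return E


def _component_index(name: str, n: int) -> int:
    parts = name.strip().split("_")
    try:
        if parts[0] == "x" and len(parts) == 2:
            i = int(parts[1])
            if 1 <= i <= n:
                return i - 1
        elif parts[0] == "a" and len(parts) == 3:
            i, j = int(parts[1]), int(parts[2])
            if 1 <= i <= n and 1 <= j <= n:
                return n + (i - 1) * n + (j - 1)
        elif parts[0] == "mu" and len(parts) == 2:
            i = int(parts[1])
            if 1 <= i <= n:
                return n + n * n + (i - 1)
    except ValueError:
        pass
    raise ParseError(f"unknown component name {name!r} for n={n}")


def read_bounds(path: str | Path, n: int) -> RangeConstraint:
    """Bounds file -> componentwise range constraint (missing = unbounded)."""
    d = augmented_dim(n)
    lo = np.full(d, -np.inf)
    hi = np.full(d, np.inf)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("component"):
                continue
            fields = line.replace(",", "\t").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 fields, got {len(fields)}")
            try:
                idx = _component_index(fields[0], n)
                lo[idx] = float(fields[1])
                hi[idx] = float(fields[2])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from e
    return RangeConstraint(lower=lo, upper=hi)


def write_benchmark_report(path: str | Path, summary: BenchmarkSummary) -> None:
    """TSV report of min/max/avg per (condition, metric), plus a JSON twin."""
    agg = summary.aggregates()
    agg.to_csv(path, sep="\t", index=False, float_format="%.6g")
    payload = {
        "runs": summary.runs,
        "base_seed": summary.base_seed,
        "tau": summary.tau,
        "diverged": [
            {"condition": c, "run": r} for c, r in summary.diverged
        ],
        "aggregates": {},
        "per_run": json.loads(summary.rows.to_json(orient="records")),
    }
    for _, row in agg.iterrows():
        payload["aggregates"].setdefault(row["condition"], {})[row["metric"]] = {
            "min": _jsonable(row["min"]),
            "max": _jsonable(row["max"]),
            "avg": _jsonable(row["avg"]),
        }
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=1))


def _jsonable(x: float):
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


def write_step_trace(path: str | Path, records, n: int) -> None:
    """Per-step convergence trace: innovation norm and parameter-block
    covariance trace, for convergence plots."""
    with open(path, "w") as fh:
        fh.write("k\tinnovation_norm\tparam_cov_trace\n")
        for r in records:
            fh.write(
                f"{r.k}\t{np.linalg.norm(r.innovation):.10g}\t"
                f"{np.trace(r.filtered.cov[n:, n:]):.10g}\n"
            )
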