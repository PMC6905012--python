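"""Pairwise Pearson correlation and hard thresholding into an edge list."""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TextIO, Union

import numpy as np
from scipy import stats

from .data_io import BiomarkerTable

__all__ = [
    "CorrelationMatrix",
    "Edge",
    "pearson_r",
    "correlation_matrix",
    "threshold_edges",
    "fisher_z_pvalue",
    "write_edge_list",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over a fixed biomarker order.

    ``n_samples`` is a single value: the pipeline enforces complete-case
    data upstream, so every pairwise coefficient uses the same n.
    """

    biomarkers: tuple[str, ...]
    rho: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        k = len(self.biomarkers)
        if self.rho.shape != (k, k):
            raise ValueError(f"rho must be {k}x{k}, got {self.rho.shape}")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-12):
            raise ValueError("rho diagonal must be 1")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("rho entries must lie in [-1, 1]")

    def get(self, a: str, b: str) -> float:
        i = self.biomarkers.index(a)
        j = self.biomarkers.index(b)
        return float(self.rho[i, j])


@dataclass(frozen=True)
class Edge:
    """An unordered supra-threshold correlation between two biomarkers.

    Construction canonicalises the endpoint order (``a < b``) so that
    ``Edge(x, y, r) == Edge(y, x, r)``.
    """

    a: str
    b: str
    rho: float
    within_group: bool

    def __new__(cls, a: str, b: str, rho: float, within_group: bool):
        if a == b:
            raise ValueError(f"self-correlation edge on {a!r}")
        obj = super().__new__(cls)
        if b < a:
            a, b = b, a
        object.__setattr__(obj, "a", a)
        object.__setattr__(obj, "b", b)
        object.__setattr__(obj, "rho", float(rho))
        object.__setattr__(obj, "within_group", bool(within_group))
        return obj

    def __init__(self, a: str, b: str, rho: float, within_group: bool):
        # all assignment happens in __new__ to allow canonical ordering
        pass

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two equal-length vectors.

    Zero variance in either vector is an error (the coefficient is
    undefined), never a silent 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.shape != ya.shape:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if xa.size < 3:
        raise ValueError(f"need at least 3 observations, got {xa.size}")
    if np.isnan(xa).any() or np.isnan(ya).any():
        raise ValueError("missing values: run drop_incomplete_biomarkers first")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance: correlation coefficient undefined")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def correlation_matrix(table: BiomarkerTable) -> CorrelationMatrix:
    """All-pairs Pearson correlations of a complete biomarker table."""
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("table has missing entries: run drop_incomplete_biomarkers")
    if vals.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got {vals.shape[0]}")
    sds = vals.std(axis=0)
    constant = [c for c, s in zip(table.values.columns, sds) if s == 0.0]
    if constant:
        raise ValueError(f"constant biomarkers (undefined correlation): {constant}")
    rho = np.corrcoef(vals, rowvar=False)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(
        biomarkers=tuple(table.values.columns),
        rho=rho,
        n_samples=vals.shape[0],
    )


def threshold_edges(
    cm: CorrelationMatrix,
    rho0: float,
    group_map: Mapping[str, str],
    strict: bool = False,
) -> list[Edge]:
    """Unordered pairs whose |rho| clears the threshold.

    The comparison is inclusive (``|rho| >= rho0``) by default; pass
    ``strict=True`` for ``|rho| > rho0``.  Edges are returned sorted
    lexicographically by (a, b).
    """
    if not (0.0 < rho0 <= 1.0):
        raise ValueError(f"rho0 must be in (0, 1], got {rho0}")
    missing = [b for b in cm.biomarkers if b not in group_map]
    if missing:
        raise ValueError(f"biomarkers without a group assignment: {missing}")
    edges: list[Edge] = []
    k = len(cm.biomarkers)
    for i in range(k):
        for j in range(i + 1, k):
            r = float(cm.rho[i, j])
            keep = abs(r) > rho0 if strict else abs(r) >= rho0
            if keep:
                a, b = cm.biomarkers[i], cm.biomarkers[j]
                edges.append(
                    Edge(a, b, r, within_group=group_map[a] == group_map[b])
                )
    edges.sort(key=lambda e: e.pair)
    return edges


def fisher_z_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for rho = 0 via the Fisher z transform.

    Offered as an optional annotation only; the pipeline filters edges by
    the |rho| threshold, never by p-value.
    """
    if n < 4:
        raise ValueError("Fisher z p-value needs n >= 4")
    if abs(r) >= 1.0:
        return 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


def write_edge_list(
    edges: Sequence[Edge],
    group_map: Mapping[str, str],
    dest: Union[str, Path, TextIO],
    delimiter: str = ",",
) -> None:
    """Write edges as delimited text, lexicographic by (a, b).

    Columns: a, b, rho, group_a, group_b, within_group.  rho is written at
    full precision; presentation rounding belongs to reports.
    """
    buf = io.StringIO()
    cols = ["a", "b", "rho", "group_a", "group_b", "within_group"]
    buf.write(delimiter.join(cols) + "\n")
    for e in sorted(edges, key=lambda e: e.pair):
        row = [
            e.a,
            e.b,
            repr(e.rho),
            group_map[e.a],
            group_map[e.b],
            str(e.within_group).lower(),
        ]
        buf.write(delimiter.join(row) + "\n")
    payload = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(payload, encoding="utf-8")
    else:
        dest.write(payload)
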