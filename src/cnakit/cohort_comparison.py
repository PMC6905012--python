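"""End-to-end pipeline per cohort, network comparison and unpaired t-tests.

The pipeline composition is fixed: drop incomplete biomarkers, compute the
full Pearson correlation matrix, threshold, build the network, collapse to
group level, and summarise each variable group.  Two cohorts are compared
descriptively (edge differences, connector differences, hub overlap); the
t-tests mirror the univariate companion analysis and are available both
from raw data and from printed summary statistics (mean, sd, n).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np
from scipy import stats

from .correlation import Edge, correlation_matrix, threshold_edges
from .data_io import AnalysisConfig, BiomarkerTable, drop_incomplete_biomarkers
from .network_metrics import (
    BiomarkerNetwork,
    GroupLevelNetwork,
    NetworkSummary,
    build_network,
    collapse_to_group_level,
    group_summary,
)

__all__ = [
    "SummaryStats",
    "TTestResult",
    "PipelineResult",
    "ComparisonReport",
    "run_pipeline",
    "compare_cohorts",
    "ttest_from_summary",
    "ttest_table",
    "write_ttest_table",
]

log = logging.getLogger("cnakit")


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and sample count on the analysed scale."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def of(cls, values: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise ValueError("need at least 2 non-missing values")
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class PipelineResult:
    """Everything one cohort's run produces, plus a small manifest."""

    network: BiomarkerNetwork
    group_level: GroupLevelNetwork
    summaries: list[NetworkSummary]
    dropped_biomarkers: list[str]
    all_edges: list[Edge]

    @property
    def total_edge_count(self) -> int:
        """All supra-threshold edges, within- and cross-group combined."""
        return self.network.n_edges

    def manifest(self) -> dict:
        return {
            "dropped_biomarkers": self.dropped_biomarkers,
            "n_nodes": self.network.n_nodes,
            "n_edges": self.network.n_edges,
            "groups": sorted(self.network.groups_present()),
        }


@dataclass
class ComparisonReport:
    """Descriptive differences between two cohort networks."""

    cohort_a: str
    cohort_b: str
    result_a: PipelineResult
    result_b: PipelineResult
    edges_only_in_a: list[Edge]
    edges_only_in_b: list[Edge]
    shared_edges: list[tuple[str, str]]
    connectors_only_in_a: list[tuple[str, str]]
    connectors_only_in_b: list[tuple[str, str]]
    shared_hubs: list[str]
    hubs_only_in_a: list[str]
    hubs_only_in_b: list[str]

    def to_dict(self) -> dict:
        def edge_rows(edges: list[Edge]) -> list[dict]:
            return [
                {"a": e.a, "b": e.b, "rho": e.rho, "within_group": e.within_group}
                for e in edges
            ]

        def summaries(result: PipelineResult) -> list[dict]:
            return [
                {
                    "group": s.group,
                    "edge_count": s.edge_count,
                    "density": s.density,
                    "hub_count": s.hub_count,
                    "hub_names": list(s.hub_names),
                }
                for s in result.summaries
            ]

        return {
            "cohorts": {
                self.cohort_a: {
                    "total_edge_count": self.result_a.total_edge_count,
                    "group_summaries": summaries(self.result_a),
                    "connectors": sorted(self.result_a.group_level.connectors),
                    "dropped_biomarkers": self.result_a.dropped_biomarkers,
                },
                self.cohort_b: {
                    "total_edge_count": self.result_b.total_edge_count,
                    "group_summaries": summaries(self.result_b),
                    "connectors": sorted(self.result_b.group_level.connectors),
                    "dropped_biomarkers": self.result_b.dropped_biomarkers,
                },
            },
            "edges_only_in": {
                self.cohort_a: edge_rows(self.edges_only_in_a),
                self.cohort_b: edge_rows(self.edges_only_in_b),
            },
            "shared_edges": [list(p) for p in self.shared_edges],
            "connectors_only_in": {
                self.cohort_a: [list(c) for c in self.connectors_only_in_a],
                self.cohort_b: [list(c) for c in self.connectors_only_in_b],
            },
            "hub_overlap": {
                "shared": self.shared_hubs,
                self.cohort_a: self.hubs_only_in_a,
                self.cohort_b: self.hubs_only_in_b,
            },
        }


def run_pipeline(
    table: BiomarkerTable, config: AnalysisConfig | None = None
) -> PipelineResult:
    """Single-cohort analysis: complete-case, correlate, threshold, summarise."""
    cfg = config or AnalysisConfig()
    complete, dropped = drop_incomplete_biomarkers(table)
    log.info(
        "pipeline: %d biomarkers in, %d dropped (complete-case), %d samples",
        len(table.biomarkers),
        len(dropped),
        table.n_samples,
    )
    cm = correlation_matrix(complete)
    edges = threshold_edges(
        cm, cfg.rho0, complete.group_map, strict=cfg.strict_threshold
    )
    log.info("pipeline: %d edges retained at |rho| >= %g", len(edges), cfg.rho0)
    net = build_network(edges, complete.group_map, provenance=cfg)
    group_level = collapse_to_group_level(net)
    summaries = []
    for name in sorted(table.groups):
        roster = table.groups[name]
        if name in net.groups_present() or net.n_nodes == 0:
            summaries.append(group_summary(net, name, roster, cfg))
        else:
            summaries.append(
                NetworkSummary(
                    group=name, edge_count=0, density=0.0, hub_count=0, hub_names=()
                )
            )
    return PipelineResult(
        network=net,
        group_level=group_level,
        summaries=summaries,
        dropped_biomarkers=dropped,
        all_edges=edges,
    )


def _hub_names(result: PipelineResult) -> set[str]:
    return {h for s in result.summaries for h in s.hub_names}


def compare_cohorts(
    table_a: BiomarkerTable,
    table_b: BiomarkerTable,
    config: AnalysisConfig | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonReport:
    """Run both pipelines and enumerate the network differences."""
    cfg = config or AnalysisConfig()
    roster_a = set(table_a.biomarkers)
    roster_b = set(table_b.biomarkers)
    if roster_a != roster_b:
        diff = sorted(roster_a.symmetric_difference(roster_b))
        raise ValueError(f"biomarker rosters differ between cohorts: {diff}")

    res_a = run_pipeline(table_a, cfg)
    res_b = run_pipeline(table_b, cfg)

    pairs_a = {e.pair: e for e in res_a.all_edges}
    pairs_b = {e.pair: e for e in res_b.all_edges}
    only_a = sorted((e for p, e in pairs_a.items() if p not in pairs_b), key=lambda e: e.pair)
    only_b = sorted((e for p, e in pairs_b.items() if p not in pairs_a), key=lambda e: e.pair)
    shared = sorted(set(pairs_a) & set(pairs_b))

    conn_a = set(res_a.group_level.connectors)
    conn_b = set(res_b.group_level.connectors)
    hubs_a = _hub_names(res_a)
    hubs_b = _hub_names(res_b)

    return ComparisonReport(
        cohort_a=label_a,
        cohort_b=label_b,
        result_a=res_a,
        result_b=res_b,
        edges_only_in_a=only_a,
        edges_only_in_b=only_b,
        shared_edges=shared,
        connectors_only_in_a=sorted(conn_a - conn_b),
        connectors_only_in_b=sorted(conn_b - conn_a),
        shared_hubs=sorted(hubs_a & hubs_b),
        hubs_only_in_a=sorted(hubs_a - hubs_b),
        hubs_only_in_b=sorted(hubs_b - hubs_a),
    )


# ---------------------------------------------------------------------------
# t-tests


def ttest_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "welch"
) -> TTestResult:
    """Two-sided unpaired t-test from summary statistics.

    ``welch`` uses the unequal-variance statistic with Welch-Satterthwaite
    degrees of freedom; ``pooled`` is the classic equal-variance test with
    df = n_a + n_b - 2.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            df = float(a.n + b.n - 2)
            return TTestResult(t=0.0, df=df, p=1.0, variant=variant)
        raise ValueError("degenerate t-test: both sds are 0 and means differ")
    t, p = stats.ttest_ind_from_stats(
        mean1=a.mean,
        std1=a.sd,
        nobs1=a.n,
        mean2=b.mean,
        std2=b.sd,
        nobs2=b.n,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(t=float(t), df=float(df), p=float(p), variant=variant)


def ttest_table(
    table_a: BiomarkerTable,
    table_b: BiomarkerTable,
    variant: str = "welch",
    significance_level: float = 0.05,
) -> list[dict]:
    """One unpaired t-test per shared biomarker.

    Missing entries are ignored per biomarker.  No multiple-testing
    correction is applied; the ``significant`` flag is the raw p-value
    against ``significance_level``.  Apply any log transform before
    calling (it is an explicit, recorded preprocessing step).
    """
    roster_a = set(table_a.biomarkers)
    roster_b = set(table_b.biomarkers)
    if roster_a != roster_b:
        diff = sorted(roster_a.symmetric_difference(roster_b))
        raise ValueError(f"biomarker rosters differ: {diff}")
    rows = []
    for b in table_a.biomarkers:
        sa = SummaryStats.of(table_a.values[b].to_numpy())
        sb = SummaryStats.of(table_b.values[b].to_numpy())
        res = ttest_from_summary(sa, sb, variant=variant)
        rows.append(
            {
                "biomarker": b,
                "group": table_a.group_map[b],
                "mean_a": sa.mean,
                "sd_a": sa.sd,
                "n_a": sa.n,
                "mean_b": sb.mean,
                "sd_b": sb.sd,
                "n_b": sb.n,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.p < significance_level,
            }
        )
    return rows


def write_ttest_table(
    rows: Sequence[dict], dest: Union[str, Path, TextIO], delimiter: str = ","
) -> None:
    """Delimited t-test table at full precision (rounding belongs to reports)."""
    cols = [
        "biomarker",
        "group",
        "mean_a",
        "sd_a",
        "n_a",
        "mean_b",
        "sd_b",
        "n_b",
        "t",
        "df",
        "p",
        "significant",
    ]
    buf = io.StringIO()
    buf.write(delimiter.join(cols) + "\n")
    for r in rows:
        cells = []
        for c in cols:
            v = r[c]
            cells.append(repr(v) if isinstance(v, float) else str(v))
        buf.write(delimiter.join(cells) + "\n")
    payload = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(payload, encoding="utf-8")
    else:
        dest.write(payload)
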