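"""Reading, validation and preprocessing of biomarker tables.

A biomarker table is a samples x biomarkers matrix of continuous
measurements, with a cohort label per sample and every biomarker assigned
to exactly one variable group.  Preprocessing consists of an optional,
explicitly recorded log transformation and a complete-case rule that drops
any biomarker column containing missing values (the sample rows are kept).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, TextIO, Union

import numpy as np
import pandas as pd

__all__ = [
    "VariableGroup",
    "LogTransform",
    "BiomarkerTable",
    "AnalysisConfig",
    "TableValidationError",
    "read_biomarker_table",
    "read_group_spec",
    "write_biomarker_table",
    "log_transform",
    "drop_incomplete_biomarkers",
]

#: cell contents treated as missing on input (compared case-insensitively)
MISSING_MARKERS = frozenset({"", "na", "nan"})

#: canonical group names; the registry is open — any name is accepted
DEFAULT_GROUP_NAMES = (
    "anthropometric",
    "metabolic",
    "immune_cell",
    "cytokine",
    "microbiome",
)


class TableValidationError(ValueError):
    """Raised when a biomarker table violates its structural contract."""


@dataclass(frozen=True)
class VariableGroup:
    """A named group of biomarkers.

    ``roster`` is the measured universe of the group, i.e. it keeps the
    names of biomarkers that are later excluded from the network by the
    complete-case rule.  Density denominators may be defined over this
    roster.
    """

    name: str
    roster: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.roster) < 1:
            raise TableValidationError(f"group {self.name!r} has an empty roster")
        if len(set(self.roster)) != len(self.roster):
            raise TableValidationError(f"group {self.name!r} has duplicate roster entries")

    @property
    def size(self) -> int:
        return len(self.roster)


@dataclass(frozen=True)
class LogTransform:
    """Record of a log transformation applied to the values."""

    base: float
    offset: float


@dataclass
class BiomarkerTable:
    """Samples x biomarkers matrix plus cohort labels and group assignments.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per biomarker.  Missing
        entries are NaN.
    cohort
        Series of cohort labels aligned with ``values``.
    groups
        Mapping group name -> :class:`VariableGroup`.  Rosters are disjoint
        and jointly cover every column of ``values`` (they may additionally
        list biomarkers that were dropped from ``values``).
    transform_log
        Transformations applied so far, oldest first.
    """

    values: pd.DataFrame
    cohort: pd.Series
    groups: dict[str, VariableGroup]
    transform_log: tuple[LogTransform, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        ids = list(self.values.index)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise TableValidationError(f"duplicate biomarker names: {dupes}")
        if not self.cohort.index.equals(self.values.index):
            raise TableValidationError("cohort labels not aligned with sample ids")
        seen: dict[str, str] = {}
        for g in self.groups.values():
            for b in g.roster:
                if b in seen:
                    raise TableValidationError(
                        f"biomarker {b!r} assigned to both {seen[b]!r} and {g.name!r}"
                    )
                seen[b] = g.name
        missing_group = [c for c in cols if c not in seen]
        if missing_group:
            raise TableValidationError(
                f"biomarkers without a group assignment: {missing_group}"
            )

    # -- views ------------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_map(self) -> dict[str, str]:
        """biomarker -> group name, restricted to present columns."""
        roster_map = {b: g.name for g in self.groups.values() for b in g.roster}
        return {b: roster_map[b] for b in self.values.columns}

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset_cohort(self, label) -> "BiomarkerTable":
        """Rows belonging to one cohort, groups and log carried over."""
        mask = self.cohort == label
        if not mask.any():
            raise TableValidationError(f"no samples with cohort label {label!r}")
        return BiomarkerTable(
            values=self.values.loc[mask].copy(),
            cohort=self.cohort.loc[mask].copy(),
            groups=dict(self.groups),
            transform_log=self.transform_log,
        )

    def cohort_labels(self) -> list:
        return sorted(self.cohort.unique().tolist(), key=str)


@dataclass(frozen=True)
class AnalysisConfig:
    """Conventions of a network analysis run.

    All defaults follow the reference analysis: inclusive |rho| >= 0.7
    edge threshold, hubs at normalized betweenness strictly above 0.1,
    density denominators over the full group roster, betweenness scored on
    within-group induced subgraphs, Welch t-tests.
    """

    rho0: float = 0.7
    strict_threshold: bool = False
    hub_bc_threshold: float = 0.1
    log_base: float = math.e
    log_offset: float = 0.0
    density_universe: str = "group_roster"  # or "connected_nodes"
    bc_scope: str = "within_group"  # or "full_network"
    ttest_variant: str = "welch"  # or "pooled"
    significance_level: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.rho0 <= 1.0):
            raise ValueError(f"rho0 must be in (0, 1], got {self.rho0}")
        if self.hub_bc_threshold < 0:
            raise ValueError("hub_bc_threshold must be >= 0")
        if self.density_universe not in ("group_roster", "connected_nodes"):
            raise ValueError(f"unknown density_universe {self.density_universe!r}")
        if self.bc_scope not in ("within_group", "full_network"):
            raise ValueError(f"unknown bc_scope {self.bc_scope!r}")
        if self.ttest_variant not in ("welch", "pooled"):
            raise ValueError(f"unknown ttest_variant {self.ttest_variant!r}")

    def to_dict(self) -> dict:
        return {
            "rho0": self.rho0,
            "strict_threshold": self.strict_threshold,
            "hub_bc_threshold": self.hub_bc_threshold,
            "log_base": self.log_base,
            "log_offset": self.log_offset,
            "density_universe": self.density_universe,
            "bc_scope": self.bc_scope,
            "ttest_variant": self.ttest_variant,
            "significance_level": self.significance_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# readers / writers


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in MISSING_MARKERS


def _coerce_cell(cell: str) -> float:
    if _is_missing(cell):
        return math.nan
    try:
        return float(cell)
    except ValueError:
        # unparseable numerics become missing entries by contract
        return math.nan


def read_group_spec(
    source: Union[str, Path, TextIO], delimiter: str = ","
) -> dict[str, str]:
    """Read a two-column (biomarker, group) file into a mapping.

    A header line ``biomarker,group`` (any case) is skipped if present.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(delimiter)]
        if len(parts) != 2:
            raise TableValidationError(
                f"group spec line {lineno}: expected 2 columns, got {len(parts)}"
            )
        name, group = parts
        if lineno == 1 and name.lower() == "biomarker" and group.lower() == "group":
            continue
        if name in mapping:
            raise TableValidationError(f"duplicate biomarker {name!r} in group spec")
        mapping[name] = group
    if not mapping:
        raise TableValidationError("empty group spec")
    return mapping


def _groups_from_map(group_map: Mapping[str, str]) -> dict[str, VariableGroup]:
    rosters: dict[str, list[str]] = {}
    for b, g in group_map.items():
        rosters.setdefault(g, []).append(b)
    return {g: VariableGroup(g, tuple(r)) for g, r in rosters.items()}


def read_biomarker_table(
    source: Union[str, Path, TextIO],
    group_spec: Mapping[str, str],
    cohort_column: str = "cohort",
    sample_column: str | None = None,
    delimiter: str = ",",
) -> BiomarkerTable:
    """Parse a delimited biomarker table.

    The first column (or ``sample_column``) holds sample ids, one column
    named ``cohort_column`` holds cohort labels, and every remaining column
    is a biomarker that must appear in ``group_spec``.  Empty cells, "NA"
    and "NaN" (case-insensitive) and unparseable numeric cells become
    missing entries.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise TableValidationError("table needs a header row and at least one sample")
    header = [h.strip() for h in lines[0].split(delimiter)]
    if sample_column is None:
        sample_column = header[0]
    for required in (sample_column, cohort_column):
        if required not in header:
            raise TableValidationError(f"column {required!r} not found in header")
    biomarker_cols = [h for h in header if h not in (sample_column, cohort_column)]
    dupes = sorted({b for b in biomarker_cols if biomarker_cols.count(b) > 1})
    if dupes:
        raise TableValidationError(f"duplicate biomarker names: {dupes}")
    unassigned = [b for b in biomarker_cols if b not in group_spec]
    if unassigned:
        raise TableValidationError(
            f"biomarkers without a group assignment: {unassigned}"
        )

    idx = {h: i for i, h in enumerate(header)}
    sample_ids: list[str] = []
    cohorts: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(delimiter)]
        if len(cells) != len(header):
            raise TableValidationError(
                f"line {lineno}: expected {len(header)} cells, got {len(cells)}"
            )
        sample_ids.append(cells[idx[sample_column]])
        cohorts.append(cells[idx[cohort_column]])
        rows.append([_coerce_cell(cells[idx[b]]) for b in biomarker_cols])

    dup_ids = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dup_ids:
        raise TableValidationError(f"duplicate sample ids: {dup_ids}")

    values = pd.DataFrame(rows, index=sample_ids, columns=biomarker_cols, dtype=float)
    cohort = pd.Series(cohorts, index=values.index, name=cohort_column)
    groups = _groups_from_map({b: group_spec[b] for b in biomarker_cols})
    return BiomarkerTable(values=values, cohort=cohort, groups=groups)


def write_biomarker_table(
    table: BiomarkerTable,
    dest: Union[str, Path, TextIO],
    delimiter: str = ",",
    cohort_column: str = "cohort",
    sample_column: str = "sample_id",
    float_format: str = "%r",
) -> None:
    """Write a table in the same dialect :func:`read_biomarker_table` reads.

    Values are serialised with ``repr`` so a read/write/read round trip is
    exact; missing entries are written as ``NA``.
    """
    buf = io.StringIO()
    header = [sample_column, cohort_column, *table.values.columns]
    buf.write(delimiter.join(header) + "\n")
    for sid, row in table.values.iterrows():
        cells = [str(sid), str(table.cohort.loc[sid])]
        for v in row:
            cells.append("NA" if pd.isna(v) else float_format % v)
        buf.write(delimiter.join(cells) + "\n")
    payload = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(payload, encoding="utf-8")
    else:
        dest.write(payload)


# ---------------------------------------------------------------------------
# transforms


def log_transform(
    table: BiomarkerTable,
    base: float = math.e,
    offset: float = 0.0,
    columns: Iterable[str] | None = None,
) -> BiomarkerTable:
    """Element-wise ``log_base(value + offset)`` over the selected columns.

    Missing entries stay missing.  Any non-positive ``value + offset``
    aborts with an error naming the offending sample and biomarker, because
    a silent NaN there would later be confused with a genuinely missing
    measurement.
    """
    if base <= 0 or base == 1:
        raise ValueError(f"invalid log base {base}")
    cols = list(columns) if columns is not None else list(table.values.columns)
    unknown = [c for c in cols if c not in table.values.columns]
    if unknown:
        raise TableValidationError(f"unknown biomarkers: {unknown}")
    vals = table.values.copy()
    shifted = vals[cols] + offset
    bad = (shifted <= 0) & vals[cols].notna()
    if bad.to_numpy().any():
        col = bad.any(axis=0).idxmax()
        sid = bad[col].idxmax()
        raise ValueError(
            f"log transform undefined: biomarker {col!r}, sample {sid!r} has "
            f"value {vals.at[sid, col]!r} (offset {offset})"
        )
    vals[cols] = np.log(shifted) / math.log(base)
    return BiomarkerTable(
        values=vals,
        cohort=table.cohort.copy(),
        groups=dict(table.groups),
        transform_log=table.transform_log + (LogTransform(base=base, offset=offset),),
    )


def drop_incomplete_biomarkers(
    table: BiomarkerTable,
) -> tuple[BiomarkerTable, list[str]]:
    """Complete-case rule at the biomarker level.

    Every biomarker column containing one or more missing entries is
    removed entirely; samples are never dropped.  Group rosters are left
    untouched so dropped biomarkers remain part of the measured universe
    (this keeps roster-based density denominators well defined).
    """
    has_missing = table.values.isna().any(axis=0)
    dropped = [c for c in table.values.columns if has_missing[c]]
    if len(dropped) == len(table.values.columns):
        raise TableValidationError(
            "every biomarker has missing data; nothing left to analyse"
        )
    if not dropped:
        return table, []
    kept = table.values.drop(columns=dropped)
    out = BiomarkerTable(
        values=kept,
        cohort=table.cohort.copy(),
        groups=dict(table.groups),
        transform_log=table.transform_log,
    )
    return out, dropped
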