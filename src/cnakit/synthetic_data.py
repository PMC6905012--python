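"""Synthetic two-cohort biomarker tables with planted correlation structure.

The generator uses a Gaussian copula: samples are drawn from a
multivariate normal with a repaired target correlation matrix and then
pushed through the configured marginal (``lognormal`` exponentiates, so
the target Pearson correlations hold exactly on the log scale where the
pipeline computes them; Pearson on the raw lognormal scale would differ,
which is intentional).

Target matrices are assembled from a plant recipe: requested pairwise
correlations form a graph, and whenever that graph is a forest the
correlations implied between non-adjacent members of a tree are filled in
as path products (the correlation structure of a Gaussian Markov tree),
which keeps the matrix positive semidefinite before any background noise
is added.  Background correlations come from a shrunk empirical
correlation matrix of pure noise — positive semidefinite by construction,
with entries confined to a near-zero shell.  Overwriting the planted
entries can break semidefiniteness slightly; an alternating-projections
nearest-correlation repair reconciles the result, and the post-repair
values at the planted positions are recorded as the ground truth.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import BiomarkerTable, VariableGroup

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Plant",
    "HubPlant",
    "nearest_correlation_repair",
    "build_target_matrix",
    "default_rosters",
    "simulate_cohort",
    "make_study_emulation",
    "write_ground_truth",
]

DEFAULT_GROUP_SIZES: tuple[tuple[str, int], ...] = (
    ("anthropometric", 8),
    ("metabolic", 12),
    ("immune_cell", 16),
    ("cytokine", 25),
    ("microbiome", 30),
)

ANTHROPOMETRIC_NAMES = (
    "age",
    "BMI",
    "waist",
    "fat_mass",
    "muscle_mass",
    "visceral_fat",
    "WHR",
    "RMR",
)

METABOLIC_NAMES = (
    "SBP",
    "DBP",
    "triglycerides",
    "cholesterol",
    "HDL",
    "LDL",
    "HbA1c",
    "glucose",
    "CRP",
    "ESR",
    "lymphocytes",
    "platelets",
)

IMMUNE_CELL_NAMES = (
    "Mast_cells",
    "NK_cells",
    "CD8_T_cells",
    "DC",
    "Treg",
    "CD45",
    "Macrophages",
    "T_cells",
    "Neutrophils",
    "Cytotoxic_cells",
    "Th1_cells",
    "Normal_mucosa",
    "T_helper_cells",
    "B_cells",
    "Th2_cells",
    "CD4_activated",
)

CYTOKINE_NAMES = ("IL6", "TNFa", "MIP1a", "MIP1b", "VEGF", "IP10", "GCSF", "PDGF")

MICROBE_NAMES = (
    "Holdemania",
    "Blautia",
    "Akkermansia",
    "Anaerostipes",
    "Flavonifractor",
    "Escherichia_Shigella",
)

#: default log-scale (location, scale) per variable group
DEFAULT_MARGINAL_PARAMS: dict[str, tuple[float, float]] = {
    "anthropometric": (3.5, 0.4),
    "metabolic": (1.5, 0.6),
    "immune_cell": (6.0, 0.5),
    "cytokine": (2.0, 0.8),
    "microbiome": (4.0, 1.0),
}


@dataclass(frozen=True)
class Plant:
    """A requested pairwise correlation between two biomarkers."""

    a: str
    b: str
    rho: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"cannot plant a self-correlation on {self.a!r}")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"planted rho must lie in (-1, 1), got {self.rho}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.a, self.b)))


@dataclass(frozen=True)
class HubPlant:
    """A star of correlations: one center, several spokes.

    With ``|rho| = 0.8`` the implied spoke-spoke correlations under the
    Markov-tree fill are at most 0.64 — below a 0.7 edge threshold — so
    the center emerges as the between-node of its star.
    """

    cohort: str
    center: str
    spokes: tuple[str, ...]
    rho: float = 0.8
    signs: tuple[int, ...] | None = None

    def expand(self) -> list[Plant]:
        signs = self.signs or tuple(1 for _ in self.spokes)
        if len(signs) != len(self.spokes):
            raise ValueError("signs must match spokes")
        return [
            Plant(self.center, s, sign * abs(self.rho))
            for s, sign in zip(self.spokes, signs)
        ]


@dataclass
class SyntheticConfig:
    """Full generative recipe for a two-cohort study."""

    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUP_SIZES
    n_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"disease": 11, "control": 12}
    )
    plants: dict[str, tuple[Plant, ...]] = field(default_factory=dict)
    hub_plants: tuple[HubPlant, ...] = ()
    target_correlation: dict[str, np.ndarray] = field(default_factory=dict)
    marginal: str = "lognormal"  # or "gaussian"
    marginal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINAL_PARAMS)
    )
    background_scale: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marginal not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown marginal {self.marginal!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.background_scale <= 0.2):
            raise ValueError("background_scale must lie in [0, 0.2]")
        roster = set()
        for g in self.rosters().values():
            roster.update(g.roster)
        for hp in self.hub_plants:
            missing = [b for b in (hp.center, *hp.spokes) if b not in roster]
            if missing:
                raise ValueError(f"hub plant references unknown biomarkers: {missing}")
        for cohort, plants in self.plants.items():
            for p in plants:
                missing = [b for b in (p.a, p.b) if b not in roster]
                if missing:
                    raise ValueError(
                        f"plant for {cohort!r} references unknown biomarkers: {missing}"
                    )

    def rosters(self) -> dict[str, VariableGroup]:
        return default_rosters(self.groups)

    def cohort_plants(self, cohort: str) -> list[Plant]:
        out = list(self.plants.get(cohort, ()))
        for hp in self.hub_plants:
            if hp.cohort == cohort:
                out.extend(hp.expand())
        return out

    def cohort_hub_centers(self, cohort: str) -> list[str]:
        return [hp.center for hp in self.hub_plants if hp.cohort == cohort]


@dataclass
class GroundTruth:
    """What was planted, with post-repair true correlations.

    ``target_correlation`` holds the full repaired target matrix per cohort
    (biomarker order as generated); it is kept in memory for recovery
    checks but excluded from the JSON export for size.
    """

    planted_edges: dict[str, tuple[tuple[str, str, float], ...]]
    planted_hubs: dict[str, tuple[str, ...]]
    seed: int
    target_correlation: dict[str, np.ndarray] = field(default_factory=dict)
    biomarker_order: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted_edges": {
                c: [[a, b, r] for a, b, r in edges]
                for c, edges in self.planted_edges.items()
            },
            "planted_hubs": {c: list(h) for c, h in self.planted_hubs.items()},
        }


def default_rosters(
    groups: Sequence[tuple[str, int]] = DEFAULT_GROUP_SIZES,
) -> dict[str, VariableGroup]:
    """Named rosters per group; well-known biomarker names first, then generic."""
    named = {
        "anthropometric": ANTHROPOMETRIC_NAMES,
        "metabolic": METABOLIC_NAMES,
        "immune_cell": IMMUNE_CELL_NAMES,
        "cytokine": CYTOKINE_NAMES,
        "microbiome": MICROBE_NAMES,
    }
    rosters = {}
    for name, size in groups:
        base = list(named.get(name, ()))[:size]
        extra = [f"{name}_{i:02d}" for i in range(len(base) + 1, size + 1)]
        rosters[name] = VariableGroup(name, tuple(base + extra))
    return rosters


# ---------------------------------------------------------------------------
# correlation matrix machinery


def nearest_correlation_repair(
    matrix: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Nearest (Frobenius) positive-semidefinite correlation matrix.

    Alternating projections between the PSD cone and the unit-diagonal
    affine set, with Dykstra's correction.  A matrix that is already a
    valid correlation matrix is returned unchanged (fixed point).
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2.0)
        x = (v * np.maximum(w, 0.0)) @ v.T
        x = (x + x.T) / 2.0
        ds = x - r
        y_next = x.copy()
        np.fill_diagonal(y_next, 1.0)
        np.clip(y_next, -1.0, 1.0, out=y_next)
        if np.max(np.abs(y_next - y)) < tol:
            y = y_next
            break
        y = y_next
    w = np.linalg.eigvalsh((y + y.T) / 2.0)
    if w.min() < -1e-6:
        raise ValueError(f"repair failed to converge: min eigenvalue {w.min():.3g}")
    out = (y + y.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def _forest_components(
    plants: Sequence[Plant],
) -> tuple[list[dict[str, list[tuple[str, float]]]], bool]:
    """Adjacency per connected component, plus whether the graph is a forest."""
    adj: dict[str, list[tuple[str, float]]] = {}
    n_edges = 0
    for p in plants:
        adj.setdefault(p.a, []).append((p.b, p.rho))
        adj.setdefault(p.b, []).append((p.a, p.rho))
        n_edges += 1
    comps = []
    seen: set[str] = set()
    is_forest = True
    for start in adj:
        if start in seen:
            continue
        comp: dict[str, list[tuple[str, float]]] = {}
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            comp[u] = adj[u]
            for v, _ in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comp_edges = sum(len(v) for v in comp.values()) // 2
        if comp_edges != len(comp) - 1:
            is_forest = False
        comps.append(comp)
    return comps, is_forest


def build_target_matrix(
    biomarkers: Sequence[str],
    plants: Sequence[Plant],
    rng: np.random.Generator,
    background_scale: float = 0.1,
    plant_tolerance: float = 0.05,
) -> np.ndarray:
    """Assemble and repair a target correlation matrix from a plant recipe.

    Raises if, after repair, any planted entry moved by more than
    ``plant_tolerance`` — a silent drift of the planted structure would
    invalidate every downstream recovery check.
    """
    names = list(biomarkers)
    if len(set(names)) != len(names):
        raise ValueError("duplicate biomarker names")
    idx = {b: i for i, b in enumerate(names)}
    k = len(names)

    seen_pairs: set[tuple[str, str]] = set()
    for p in plants:
        if p.pair in seen_pairs:
            raise ValueError(f"duplicate plant for pair {p.pair}")
        seen_pairs.add(p.pair)

    # PSD background: shrunk empirical correlation of pure noise
    if background_scale > 0.0:
        m = max(k + 1, math.ceil(4.0 / background_scale**2))
        noise = rng.standard_normal((m, k))
        target = np.corrcoef(noise, rowvar=False)
    else:
        target = np.eye(k)

    # implied path products inside planted trees (PSD by the Markov property);
    # for components with cycles this is a spanning-tree fill that the PSD
    # repair then reconciles with the directly planted entries
    comps, _is_forest = _forest_components(plants)
    # background is confined to non-planted nodes: the target then splits
    # into planted blocks plus a background block, keeping it (near-)PSD so
    # the repair cannot drag the planted values away from the recipe
    planted_nodes = [idx[v] for comp in comps for v in comp]
    target[planted_nodes, :] = 0.0
    target[:, planted_nodes] = 0.0
    np.fill_diagonal(target, 1.0)
    for comp in comps:
        for root in comp:
            prod = {root: 1.0}
            stack = [root]
            while stack:
                u = stack.pop()
                for v, r in comp[u]:
                    if v not in prod:
                        prod[v] = prod[u] * r
                        stack.append(v)
            for other, value in prod.items():
                if other != root:
                    target[idx[root], idx[other]] = value
                    target[idx[other], idx[root]] = value
    for p in plants:
        target[idx[p.a], idx[p.b]] = p.rho
        target[idx[p.b], idx[p.a]] = p.rho
    np.fill_diagonal(target, 1.0)

    repaired = nearest_correlation_repair(target)
    for p in plants:
        got = repaired[idx[p.a], idx[p.b]]
        if abs(got - p.rho) > plant_tolerance:
            raise ValueError(
                f"PSD repair moved plant ({p.a}, {p.b}) from {p.rho} to {got:.4f}"
            )
    return repaired


def sample_exact_correlation(
    target: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """An n x k data matrix whose *empirical* correlation equals ``target``.

    Draws white noise, empirically whitens it, then colors with the target
    factor — useful for constructing fixtures where the thresholded edge
    set must be known deterministically rather than in distribution.
    Requires ``n > k`` and a strictly positive definite target.
    """
    target = np.asarray(target, dtype=float)
    k = target.shape[0]
    if n <= k:
        raise ValueError(f"need n > k for exact whitening, got n={n}, k={k}")
    x = rng.standard_normal((n, k))
    x -= x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    white = x @ np.linalg.inv(np.linalg.cholesky(cov)).T
    jitter = target + 1e-12 * np.eye(k)
    return white @ np.linalg.cholesky(jitter).T


# ---------------------------------------------------------------------------
# sampling


def _cohort_rng(seed: int, cohort: str) -> np.random.Generator:
    digest = hashlib.sha256(cohort.encode("utf-8")).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed, int.from_bytes(digest[:8], "big")])
    )


def simulate_cohort(
    cfg: SyntheticConfig,
    cohort: str,
    n_override: int | None = None,
) -> tuple[BiomarkerTable, GroundTruth]:
    """Draw one cohort's biomarker table from the configured recipe.

    Fully deterministic in ``(cfg.seed, cohort)``; ``n_override`` inflates
    the sample count without touching the correlation structure (used by
    recovery tests).
    """
    if cohort not in cfg.n_per_cohort:
        raise ValueError(
            f"unknown cohort {cohort!r}; configured: {sorted(cfg.n_per_cohort)}"
        )
    n = n_override if n_override is not None else cfg.n_per_cohort[cohort]
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    rosters = cfg.rosters()
    order = [b for g, _ in cfg.groups for b in rosters[g].roster]
    idx = {b: i for i, b in enumerate(order)}
    group_of = {b: g.name for g in rosters.values() for b in g.roster}

    rng = _cohort_rng(cfg.seed, cohort)
    plants = cfg.cohort_plants(cohort)
    if cohort in cfg.target_correlation:
        target = np.asarray(cfg.target_correlation[cohort], dtype=float)
        if target.shape != (len(order), len(order)):
            raise ValueError(
                f"explicit target matrix must be {len(order)}x{len(order)}"
            )
        target = nearest_correlation_repair(target)
    else:
        target = build_target_matrix(
            order, plants, rng, background_scale=cfg.background_scale
        )

    # sample via eigen factor (rank-robust where Cholesky may fail on PSD)
    w, v = np.linalg.eigh(target)
    factor = v * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n, len(order))) @ factor.T

    values = np.empty_like(z)
    for b in order:
        g = group_of[b]
        loc, scale = cfg.marginal_params.get(g, (0.0, 1.0))
        col = loc + scale * z[:, idx[b]]
        values[:, idx[b]] = np.exp(col) if cfg.marginal == "lognormal" else col

    if cfg.missing_rate > 0.0:
        mask = rng.uniform(size=values.shape) < cfg.missing_rate
        values[mask] = np.nan

    sample_ids = [f"{cohort}_{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(values, index=sample_ids, columns=order)
    table = BiomarkerTable(
        values=frame,
        cohort=pd.Series([cohort] * n, index=frame.index, name="cohort"),
        groups=rosters,
    )
    truth = GroundTruth(
        planted_edges={
            cohort: tuple(
                (*p.pair, float(target[idx[p.a], idx[p.b]])) for p in plants
            )
        },
        planted_hubs={cohort: tuple(cfg.cohort_hub_centers(cohort))},
        seed=cfg.seed,
        target_correlation={cohort: target},
        biomarker_order=tuple(order),
    )
    return table, truth


# ---------------------------------------------------------------------------
# the two-cohort study emulation


def study_emulation_config(seed: int = 0, missing_rate: float = 0.0) -> SyntheticConfig:
    """Recipe mirroring the qualitative case/control structure.

    Disease cohort: three immune hub centers (Treg, neutrophils, cytotoxic
    cells) whose stars form a tree, plus one cross-group plant for every
    one of the ten group pairs.  Control cohort: no hubs, and no
    immune-anthropometric or immune-metabolic connectivity; the other
    eight group pairs each get one plant.
    """
    hub_plants = (
        HubPlant(
            "disease",
            center="Treg",
            spokes=("Neutrophils", "Cytotoxic_cells", "MIP1b"),
            rho=0.8,
            signs=(1, -1, 1),
        ),
        HubPlant(
            "disease",
            center="Neutrophils",
            spokes=("Macrophages", "NK_cells", "Holdemania", "Blautia"),
            rho=0.8,
        ),
        HubPlant(
            "disease",
            center="Cytotoxic_cells",
            spokes=("Th1_cells", "T_cells", "CD8_T_cells"),
            rho=0.8,
            signs=(-1, -1, -1),
        ),
    )
    disease_pairs = (
        # cross-group plants covering every remaining group pair
        Plant("age", "Th2_cells", -0.8),  # anthropometric-immune
        Plant("SBP", "Mast_cells", 0.8),  # metabolic-immune
        Plant("BMI", "DBP", 0.8),  # anthropometric-metabolic
        Plant("fat_mass", "IL6", 0.8),  # anthropometric-cytokine
        Plant("waist", "Akkermansia", -0.8),  # anthropometric-microbiome
        Plant("triglycerides", "TNFa", 0.8),  # metabolic-cytokine
        Plant("HDL", "Anaerostipes", 0.8),  # metabolic-microbiome
        Plant("VEGF", "Flavonifractor", 0.8),  # cytokine-microbiome
        # within-group pairs outside the immune stars
        Plant("cholesterol", "LDL", 0.85),
        Plant("Mast_cells", "T_helper_cells", -0.8),
    )
    control_pairs = (
        # all group pairs except immune-anthropometric and immune-metabolic
        Plant("BMI", "SBP", 0.8),  # anthropometric-metabolic
        Plant("muscle_mass", "GCSF", 0.8),  # anthropometric-cytokine
        Plant("RMR", "Blautia", 0.8),  # anthropometric-microbiome
        Plant("glucose", "IP10", 0.8),  # metabolic-cytokine
        Plant("CRP", "Escherichia_Shigella", 0.8),  # metabolic-microbiome
        Plant("IL6", "Holdemania", 0.8),  # cytokine-microbiome
        Plant("DC", "MIP1a", 0.8),  # immune-cytokine
        Plant("B_cells", "Akkermansia", 0.8),  # immune-microbiome
        # isolated within-group pairs: degree-1 components, so no hubs
        Plant("Mast_cells", "T_helper_cells", -0.8),
        Plant("NK_cells", "CD8_T_cells", 0.8),
        Plant("cholesterol", "LDL", 0.85),
    )
    return SyntheticConfig(
        plants={"disease": disease_pairs, "control": control_pairs},
        hub_plants=hub_plants,
        seed=seed,
        missing_rate=missing_rate,
    )


#: group pairs deliberately left unconnected in the emulated control cohort
CONTROL_ABSENT_CONNECTORS = (
    ("anthropometric", "immune_cell"),
    ("immune_cell", "metabolic"),
)


def make_study_emulation(
    seed: int = 0,
    n_disease: int = 11,
    n_control: int = 12,
    missing_rate: float = 0.0,
) -> tuple[BiomarkerTable, BiomarkerTable, GroundTruth]:
    """Two cohort tables plus ground truth, mirroring the study design."""
    cfg = study_emulation_config(seed=seed, missing_rate=missing_rate)
    cfg.n_per_cohort = {"disease": n_disease, "control": n_control}
    disease, truth_d = simulate_cohort(cfg, "disease")
    control, truth_c = simulate_cohort(cfg, "control")
    truth = GroundTruth(
        planted_edges={**truth_d.planted_edges, **truth_c.planted_edges},
        planted_hubs={**truth_d.planted_hubs, **truth_c.planted_hubs},
        seed=seed,
        target_correlation={
            **truth_d.target_correlation,
            **truth_c.target_correlation,
        },
        biomarker_order=truth_d.biomarker_order,
    )
    return disease, control, truth


def write_ground_truth(truth: GroundTruth, dest: str | Path) -> None:
    Path(dest).write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
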