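"""Small packaged reference fixtures for tests and examples.

``IMMUNE_EDGE_FIXTURE`` is an 8-edge within-group immune-cell correlation
network published in the obesity / metabolic-syndrome literature; the
values are the reported pairwise Pearson coefficients.  It is the standard
worked example for the graph metrics (e.g. the raw betweenness of Treg on
this graph is 12, normalized 12/21).
"""

from __future__ import annotations

from .correlation import Edge

__all__ = ["IMMUNE_EDGE_FIXTURE", "immune_fixture_edges", "IMMUNE_GROUP_MAP"]

#: (a, b, rho) — all pairs within the immune_cell variable group
IMMUNE_EDGE_FIXTURE: tuple[tuple[str, str, float], ...] = (
    ("Treg", "Neutrophils", 0.73),
    ("Treg", "Cytotoxic_cells", -0.73),
    ("Treg", "T_cells", -0.74),
    ("Neutrophils", "Macrophages", 0.80),
    ("Neutrophils", "NK_cells", 0.74),
    ("Cytotoxic_cells", "Th1_cells", 0.78),
    ("Cytotoxic_cells", "T_cells", 0.77),
    ("Cytotoxic_cells", "CD8_T_cells", 0.74),
)

IMMUNE_GROUP_MAP: dict[str, str] = {
    name: "immune_cell"
    for pair in IMMUNE_EDGE_FIXTURE
    for name in (pair[0], pair[1])
}


def immune_fixture_edges() -> list[Edge]:
    """The fixture as :class:`~cnakit.correlation.Edge` objects."""
    return [Edge(a, b, rho, within_group=True) for a, b, rho in IMMUNE_EDGE_FIXTURE]
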