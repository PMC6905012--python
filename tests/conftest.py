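import numpy as np
import pandas as pd
import pytest

from cnakit.data_io import AnalysisConfig, BiomarkerTable, VariableGroup
from cnakit.fixtures import IMMUNE_GROUP_MAP, immune_fixture_edges
from cnakit.network_metrics import build_network


def make_table(values: dict, cohort=None, group_map=None, sample_ids=None):
    """Construct a small BiomarkerTable from column dict (test convenience)."""
    frame = pd.DataFrame(values, dtype=float)
    if sample_ids is not None:
        frame.index = sample_ids
    else:
        frame.index = [f"s{i}" for i in range(len(frame))]
    if cohort is None:
        cohort = ["x"] * len(frame)
    if group_map is None:
        group_map = {c: "g1" for c in frame.columns}
    rosters: dict[str, list[str]] = {}
    for b, g in group_map.items():
        rosters.setdefault(g, []).append(b)
    groups = {g: VariableGroup(g, tuple(r)) for g, r in rosters.items()}
    return BiomarkerTable(
        values=frame,
        cohort=pd.Series(cohort, index=frame.index, name="cohort"),
        groups=groups,
    )


@pytest.fixture
def immune_net():
    """The 8-edge published immune-cell correlation network."""
    return build_network(immune_fixture_edges(), IMMUNE_GROUP_MAP)


@pytest.fixture
def default_config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
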