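import pytest

from deltateams.graph_core import WeightedGraph
from deltateams.synth_oracle import (
    max_matrix_counterexample,
    toy_family_instance,
    toy_shared_instance,
)


@pytest.fixture
def toy_pair():
    """Hand-crafted 7-vertex graph pair with teams {d,f} / {c,d,f} / {a,c,d,f,g}."""
    return toy_shared_instance()


@pytest.fixture
def toy_family_pair():
    return toy_family_instance()


@pytest.fixture
def counterexample_pair():
    return max_matrix_counterexample()


@pytest.fixture
def chain_graph():
    """Path a-b-c with weights 2, 3."""
    return WeightedGraph.from_edges([("a", "b", 2), ("b", "c", 3)], name="chain")


def nontrivial(teams):
    """Teams of size >= 2 from a TeamPartition.teams tuple."""
    return [t for t in teams if len(t) > 1]
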