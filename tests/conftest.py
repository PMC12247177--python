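import pytest

from ancspatial import SpatialGraph, lattice_graph, load_anc_table


@pytest.fixture(scope="session")
def anc_table():
    return load_anc_table()


@pytest.fixture
def four_cycle():
    """Cycle a-b-c-d-a: the canonical checkerboard worked example."""
    edges = {
        frozenset(p)
        for p in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
    }
    return SpatialGraph(["a", "b", "c", "d"], edges)


@pytest.fixture(scope="session")
def lattice_8x8():
    return lattice_graph(8, 8)

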