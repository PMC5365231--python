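import pytest

from pathrank import CostConfig, CostedGraph, Network


@pytest.fixture
def diamond_costed() -> CostedGraph:
    """s→a→t with costs 1,1 and s→b→t with costs 2,2: two loopless paths."""
    return CostedGraph(
        ["s", "a", "b", "t"],
        [("s", "a", 1.0), ("a", "t", 1.0), ("s", "b", 2.0), ("b", "t", 2.0)],
    )


@pytest.fixture
def diamond_additive() -> Network:
    """Same diamond as an additive-weighted network."""
    return Network(
        nodes={"s", "a", "b", "t"},
        edges={("s", "a"): 1.0, ("a", "t"): 1.0, ("s", "b"): 2.0, ("b", "t"): 2.0},
    )


@pytest.fixture
def diamond_unweighted() -> Network:
    return Network(
        nodes={"s", "a", "b", "t"},
        edges={("s", "a"): None, ("a", "t"): None, ("s", "b"): None, ("b", "t"): None},
    )


@pytest.fixture
def probability_net() -> Network:
    """Small reliability-weighted network with several s→t paths."""
    return Network(
        nodes={"s", "a", "b", "c", "t"},
        edges={
            ("s", "a"): 0.9,
            ("a", "t"): 0.8,
            ("s", "b"): 0.5,
            ("b", "t"): 0.5,
            ("a", "b"): 0.7,
            ("b", "c"): 0.9,
            ("c", "t"): 0.9,
        },
    )


@pytest.fixture
def unweighted_config() -> CostConfig:
    return CostConfig("unweighted")
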