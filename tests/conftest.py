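import pytest

from pathcover import Dag, Instance


@pytest.fixture
def diamond() -> Dag:
    """1 -> {2,3} -> 4; the smallest width-2 DAG."""
    return Dag({"1", "2", "3", "4"}, {("1", "2"), ("1", "3"), ("2", "4"), ("3", "4")})


@pytest.fixture
def weighted_diamond() -> Dag:
    """Diamond with a cheap upper branch (1-2-4) and expensive lower one."""
    return Dag(
        {"1", "2", "3", "4"},
        {("1", "2"), ("1", "3"), ("2", "4"), ("3", "4")},
        {("1", "2"): 1.0, ("2", "4"): 1.0, ("1", "3"): 10.0, ("3", "4"): 10.0},
    )


@pytest.fixture
def chain() -> Dag:
    return Dag({"1", "2", "3"}, {("1", "2"), ("2", "3")})


@pytest.fixture
def chain5() -> Dag:
    nodes = {str(i) for i in range(1, 6)}
    edges = {(str(i), str(i + 1)) for i in range(1, 5)}
    return Dag(nodes, edges)


def make_instance(dag: Dag, **kwargs) -> Instance:
    return Instance(dag.copy(), **kwargs)
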