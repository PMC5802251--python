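import pytest

from safetigs import Digraph, fixture, random_strongly_connected


@pytest.fixture
def triangle() -> Digraph:
    return fixture("cycle", n=3)


@pytest.fixture
def bowtie() -> Digraph:
    return fixture("bowtie")


@pytest.fixture
def chorded_triangle() -> Digraph:
    return fixture("chorded_triangle")


@pytest.fixture
def two_node_cycle() -> Digraph:
    return fixture("two_node_cycle")


def random_family(count: int, max_n: int = 8) -> list[Digraph]:
    """A deterministic family of random strongly connected digraphs with
    2 <= n <= max_n and up to ~n extra edges beyond the backbone cycle."""
    out = []
    for s in range(count):
        n = 2 + s % (max_n - 1)
        extra = (3 * s) % (n + 1)
        out.append(random_strongly_connected(n, extra, seed=1000 + s))
    return out


@pytest.fixture(scope="session")
def small_random_graphs() -> list[Digraph]:
    return random_family(40)
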