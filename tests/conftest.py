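import networkx as nx
import pytest

from herbnet.simulate import SyntheticScenario, write_scenario_bundle


@pytest.fixture(scope="session")
def scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def bundle(scenario, tmp_path_factory):
    """A full synthetic input bundle on disk plus its truth manifest."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = write_scenario_bundle(scenario, outdir)
    return outdir, manifest


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


def random_graph(rng, n: int, p: float) -> nx.Graph:
    """Erdos-Renyi graph drawn from an explicit generator (deterministic)."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
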