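import numpy as np
import pytest

from biofilmnet import AbundanceTable
from biofilmnet.tables import Lineage


@pytest.fixture
def small_counts() -> AbundanceTable:
    """6 taxa x 8 samples count table with mild structure."""
    rng = np.random.default_rng(42)
    vals = rng.poisson(50, size=(6, 8)).astype(float) + 1
    tax = {
        f"T{i}": Lineage(domain=d, phylum=f"P{i % 2}", genus=f"G{i}")
        for i, d in enumerate(
            ["Bacteria", "Bacteria", "Bacteria", "Archaea", "Eukaryota", "Eukaryota"]
        )
    }
    return AbundanceTable(
        vals, [f"T{i}" for i in range(6)], [f"S{j}" for j in range(8)],
        kind="counts", taxonomy=tax,
    )


def random_signed_graph(rng: np.random.Generator, max_nodes: int = 30):
    """Random graph with mixed-sign weights, as a CooccurrenceGraph."""
    import networkx as nx

    from biofilmnet.network import CooccurrenceGraph

    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    h = nx.Graph()
    h.add_nodes_from(f"N{i}" for i in range(n))
    for u, v in g.edges():
        w = float(rng.uniform(-1, 1))
        if w == 0:
            w = 0.5
        h.add_edge(f"N{u}", f"N{v}", weight=w, sign=1 if w > 0 else -1)
    return CooccurrenceGraph(h)
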