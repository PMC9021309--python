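import networkx as nx
import numpy as np
import pytest

from biofilmnet import (
    AssociationMatrix,
    build_graph,
    centralities,
    cross_domain_edges,
    ensemble_average,
    largest_component,
    prune,
)
from biofilmnet.network import CooccurrenceGraph
from biofilmnet.tables import Lineage

from .conftest import random_signed_graph
from .oracles import betweenness_oracle, prune_oracle


def _assoc(vals, method="ensemble", taxa=None):
    vals = np.asarray(vals, dtype=float)
    taxa = taxa or [f"T{i}" for i in range(vals.shape[0])]
    return AssociationMatrix(vals, taxa, method, 10)


def _graph_from_edges(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w), sign=1 if w > 0 else -1)
    return CooccurrenceGraph(g)


class TestEnsembleAverage:
    def test_idempotent_on_identical_matrices(self):
        m = _assoc([[1, 0.4, 0.2], [0.4, 1, -0.3], [0.2, -0.3, 1]])
        out = ensemble_average([m, m, m])
        np.testing.assert_allclose(out.values, m.values)
        assert out.method == "ensemble"

    def test_plus_minus_zero_averages_to_zero(self):
        mats = [
            _assoc([[1, w], [w, 1]]) for w in (1.0, -1.0, 0.0)
        ]
        out = ensemble_average(mats)
        assert out.values[0, 1] == 0.0

    def test_weighted_mean_hand_value(self):
        mats = [_assoc([[1, v], [v, 1]]) for v in (0.6, 0.0, 0.2)]
        out = ensemble_average(mats, weights=[2, 1, 1])
        assert out.values[0, 1] == pytest.approx(0.35)

    def test_taxon_mismatch_rejected(self):
        a = _assoc(np.eye(2), taxa=["A", "B"])
        b = _assoc(np.eye(2), taxa=["A", "C"])
        with pytest.raises(ValueError, match="mismatch"):
            ensemble_average([a, b])


class TestBuildGraph:
    def test_zero_threshold_complete_minus_zero_pairs(self):
        m = _assoc([[1, 0.5, 0.0], [0.5, 1, -0.2], [0.0, -0.2, 1]])
        g = build_graph(m, 0.0)
        assert g.n_edges == 2  # the exact-zero pair is absent

    def test_threshold_above_max_weight_gives_edgeless(self):
        m = _assoc([[1, 0.5], [0.5, 1]])
        assert build_graph(m, 0.9).n_edges == 0

    def test_threshold_count_by_enumeration(self):
        m = _assoc([[1, 0.5, 0.25], [0.5, 1, -0.4], [0.25, -0.4, 1]])
        g = build_graph(m, 0.3)
        assert g.n_edges == 2  # |0.5| and |-0.4| pass, |0.25| does not

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            build_graph(_assoc(np.eye(2)), -0.1)

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        p = 8
        vals = rng.uniform(-1, 1, (p, p))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        m = _assoc(vals)
        counts = [build_graph(m, tau).n_edges for tau in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPrune:
    def test_positive_triangle_unchanged(self):
        g = _graph_from_edges([("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.3)])
        out = prune(g)
        assert out.n_nodes == 3 and out.n_edges == 3

    def test_triangle_with_negative_edge_collapses(self):
        g = _graph_from_edges([("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", -0.3)])
        out = prune(g)
        assert out.n_nodes == 0

    def test_positive_star_collapses(self):
        g = _graph_from_edges([("hub", f"leaf{i}", 0.5) for i in range(5)])
        assert prune(g).n_nodes == 0

    def test_matches_iterative_deletion_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            g = random_signed_graph(rng, max_nodes=30)
            ours = prune(g).graph
            ref = prune_oracle(g.graph)
            assert set(ours.nodes()) == set(ref.nodes())
            assert set(map(frozenset, ours.edges())) == set(map(frozenset, ref.edges()))


class TestLargestComponent:
    def test_connected_graph_returned_whole(self):
        g = _graph_from_edges([("A", "B", 1), ("B", "C", 1)])
        assert largest_component(g).n_nodes == 3

    def test_size_tie_broken_by_edges(self):
        edges = [("A", "B", 1), ("B", "C", 1), ("C", "D", 1), ("D", "A", 1)]
        edges += [("E", "F", 1), ("F", "G", 1), ("G", "H", 1), ("H", "E", 1), ("E", "G", 1)]
        out = largest_component(_graph_from_edges(edges))
        assert set(out.graph.nodes()) == {"E", "F", "G", "H"}
        assert out.n_edges == 5

    def test_full_tie_broken_lexicographically(self):
        edges = [("X", "Y", 1), ("A", "B", 1)]
        out = largest_component(_graph_from_edges(edges))
        assert set(out.graph.nodes()) == {"A", "B"}

    def test_empty_graph_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            out = largest_component(CooccurrenceGraph())
        assert out.n_nodes == 0
        assert "empty" in caplog.text


class TestCentralities:
    def test_complete_graph_zero_node_betweenness(self):
        g = CooccurrenceGraph(nx.complete_graph(4))
        rep = centralities(g)
        assert all(v == 0 for v in rep.node_betweenness.values())
        assert all(d == 3 for d in rep.node_degree.values())

    def test_path_middle_node(self):
        g = _graph_from_edges([("A", "B", 1), ("B", "C", 1)])
        rep = centralities(g)
        # normalized by (n-1)(n-2)/2 = 1 for n = 3
        assert rep.node_betweenness["B"] == pytest.approx(1.0)

    def test_star_center_unnormalized_value(self):
        k = 6
        g = _graph_from_edges([("hub", f"L{i}", 1) for i in range(k)])
        rep = centralities(g)
        norm = (k + 1 - 1) * (k + 1 - 2) / 2
        assert rep.node_betweenness["hub"] * norm == pytest.approx(k * (k - 1) / 2)

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = random_signed_graph(rng, max_nodes=12)
            rep = centralities(g)
            nb_ref, eb_ref = betweenness_oracle(g.graph)
            n = g.n_nodes
            norm = (n - 1) * (n - 2) / 2 if n > 2 else 1
            for node, val in nb_ref.items():
                assert rep.node_betweenness[node] == pytest.approx(val / norm, abs=1e-9)
            for edge, val in eb_ref.items():
                assert rep.edge_betweenness[edge] == pytest.approx(val, abs=1e-9)


class TestCrossDomain:
    def _with_domains(self, edges, domains):
        g = _graph_from_edges(edges)
        for n, d in domains.items():
            g.graph.nodes[n]["domain"] = d
        return g

    def test_single_domain_zero_cross(self):
        g = self._with_domains(
            [("A", "B", 1), ("B", "C", 1)], {"A": "Bacteria", "B": "Bacteria", "C": "Bacteria"}
        )
        df = cross_domain_edges(g)
        assert df.attrs["between"] == 0 and df.attrs["within"] == 2

    def test_bipartite_across_domains_all_cross(self):
        g = self._with_domains(
            [("B1", "E1", 1), ("B1", "E2", 1), ("B2", "E1", 1)],
            {"B1": "Bacteria", "B2": "Bacteria", "E1": "Eukaryota", "E2": "Eukaryota"},
        )
        df = cross_domain_edges(g)
        assert df.attrs["between"] == 3 and df.attrs["within"] == 0

    def test_missing_taxonomy_rejected(self):
        g = _graph_from_edges([("A", "B", 1)])
        with pytest.raises(ValueError, match="domain"):
            cross_domain_edges(g)
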