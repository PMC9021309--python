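"""Ensemble co-occurrence graph: averaging, thresholding, pruning, centralities.

The co-occurrence graph is built from the element-wise average of the three
association matrices (Spearman, SparCC, neighborhood selection), thresholded
on absolute weight.  Pruning follows the mutualistic-clique rule: negative
edges are removed first, then nodes of degree < 2 are discarded repeatedly
until a fixpoint — the 2-core of the positive-edge subgraph.  Centralities
(degree, node and edge betweenness) are computed on the unweighted topology,
since association weights are affinities rather than distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .tables import Lineage

log = logging.getLogger(__name__)


@dataclass
class CooccurrenceGraph:
    """Undirected weighted graph over taxa with taxonomy node attributes.

    Edges carry ``weight`` (signed), ``sign`` (+1/-1) and, when built from an
    ensemble, the list of contributing estimators.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- convenience -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "CooccurrenceGraph":
        return CooccurrenceGraph(self.graph.copy())

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    # -- serialization ----------------------------------------------
    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def read_graphml(cls, path) -> "CooccurrenceGraph":
        return cls(nx.read_graphml(path))

    def write_edgelist_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("taxon_a\ttaxon_b\tweight\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.10g}\n")


def ensemble_average(
    mats: list[AssociationMatrix], weights: list[float] | None = None
) -> AssociationMatrix:
    """Element-wise (optionally weighted) mean of association matrices.

    All matrices must share the taxon set and ordering and be normalized to
    [-1, 1]; the result is symmetric with unit diagonal and tagged
    ``ensemble``.
    """
    if not mats:
        raise ValueError("need at least one association matrix")
    taxa = mats[0].taxon_ids
    for m in mats[1:]:
        if m.taxon_ids != taxa:
            raise ValueError("association matrices have mismatched taxon sets")
    if weights is None:
        weights = [1.0] * len(mats)
    if len(weights) != len(mats):
        raise ValueError("one weight per matrix required")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    stacked = np.stack([m.values for m in mats])
    avg = np.tensordot(w / w.sum(), stacked, axes=1)
    avg = np.clip((avg + avg.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(avg, 1.0)
    n = max(m.n_samples for m in mats)
    return AssociationMatrix(avg, list(taxa), "ensemble", n)


def build_graph(
    ensemble: AssociationMatrix,
    edge_threshold: float = 0.3,
    taxonomy: dict[str, Lineage] | None = None,
) -> CooccurrenceGraph:
    """Threshold an association matrix into a co-occurrence graph.

    An edge joins every taxon pair with ``|weight| >= edge_threshold``; the
    signed weight is retained.  Nodes carry domain/phylum/genus attributes
    when taxonomy is supplied.
    """
    if edge_threshold < 0:
        raise ValueError("edge_threshold must be non-negative")
    g = nx.Graph()
    taxa = ensemble.taxon_ids
    for t in taxa:
        attrs = {}
        if taxonomy and t in taxonomy:
            lin = taxonomy[t]
            attrs = {"domain": lin.domain, "phylum": lin.phylum, "genus": lin.genus}
        g.add_node(t, **attrs)
    vals = ensemble.values
    p = len(taxa)
    for i in range(p):
        for j in range(i + 1, p):
            w = vals[i, j]
            if w != 0.0 and abs(w) >= edge_threshold:
                g.add_edge(taxa[i], taxa[j], weight=float(w), sign=1 if w > 0 else -1)
    return CooccurrenceGraph(g)


def prune(graph: CooccurrenceGraph) -> CooccurrenceGraph:
    """Mutualistic 2-core: drop negative edges, then iterate away degree-<2 nodes.

    Negative edges are removed first (only co-presence edges are kept), then
    nodes with fewer than two remaining edges are discarded repeatedly until
    every surviving node has degree >= 2.  May return an empty graph.
    """
    g = graph.graph.copy()
    neg = [(u, v) for u, v, d in g.edges(data=True) if d["weight"] <= 0]
    g.remove_edges_from(neg)
    core = nx.k_core(g, k=2)
    return CooccurrenceGraph(nx.Graph(core))


def largest_component(graph: CooccurrenceGraph) -> CooccurrenceGraph:
    """The connected component with the most nodes.

    Ties break by edge count, then by lexicographically smallest member
    taxon ID.  An empty input returns an empty graph (with a warning).
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        log.warning("largest_component: empty graph")
        return CooccurrenceGraph(nx.Graph())
    comps = [g.subgraph(c).copy() for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-c.number_of_nodes(), -c.number_of_edges(), min(c.nodes)))
    return CooccurrenceGraph(comps[0])


@dataclass
class CentralityReport:
    """Degree and shortest-path betweenness centralities.

    Node betweenness is normalized by (n-1)(n-2)/2 (values in [0, 1]); edge
    betweenness is the raw shortest-path count fraction (unnormalized).
    Shortest paths are unweighted.
    """

    node_degree: dict[str, int]
    node_betweenness: dict[str, float]
    edge_betweenness: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, self.node_degree[t], self.node_betweenness[t])
            for t in sorted(self.node_degree)
        ]
        return pd.DataFrame(rows, columns=["taxon_id", "degree", "betweenness"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def centralities(graph: CooccurrenceGraph) -> CentralityReport:
    """Degree, normalized node betweenness, and raw edge betweenness."""
    g = graph.graph
    degree = {n: int(d) for n, d in g.degree()}
    node_btw = nx.betweenness_centrality(g, normalized=True)
    edge_btw = nx.edge_betweenness_centrality(g, normalized=False)
    edge_btw = {tuple(sorted(e)): v for e, v in edge_btw.items()}
    return CentralityReport(degree, dict(node_btw), edge_btw)


def cross_domain_edges(graph: CooccurrenceGraph) -> pd.DataFrame:
    """Within- vs between-domain edge summary.

    Returns one row per edge with the two domains and the weight; the
    aggregate counts are in the attrs ``within`` / ``between`` of the frame.
    Requires domain attributes on every node.
    """
    g = graph.graph
    missing = [n for n, d in g.nodes(data=True) if "domain" not in d]
    if missing:
        raise ValueError(f"taxonomy (domain) missing for nodes: {missing[:5]}")
    rows = []
    within = between = 0
    for u, v, d in sorted(g.edges(data=True)):
        du, dv = g.nodes[u]["domain"], g.nodes[v]["domain"]
        cross = du != dv
        within += not cross
        between += cross
        rows.append((u, v, du, dv, d["weight"], cross))
    df = pd.DataFrame(
        rows, columns=["taxon_a", "taxon_b", "domain_a", "domain_b", "weight", "cross_domain"]
    )
    df.attrs["within"] = within
    df.attrs["between"] = between
    return df
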