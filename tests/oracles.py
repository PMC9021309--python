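"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths they check.
"""

from collections import deque

import networkx as nx


def prune_oracle(graph: nx.Graph) -> nx.Graph:
    """Iterative-deletion reference for the mutualistic 2-core.

    Removes negative edges, then repeatedly deletes any node of degree < 2
    until none remains.
    """
    g = graph.copy()
    for u, v, d in list(g.edges(data=True)):
        if d["weight"] <= 0:
            g.remove_edge(u, v)
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes()):
            if g.degree(n) < 2:
                g.remove_node(n)
                changed = True
    return g


def betweenness_oracle(graph: nx.Graph):
    """Exhaustive shortest-path enumeration of node and edge betweenness.

    For every ordered pair (s, t) all shortest paths are enumerated by BFS
    back-tracking; each intermediate node and each edge on a shortest path
    gets credit 1/(number of shortest s-t paths).  Unordered pairs counted
    once.  Returns (node_betweenness_raw, edge_betweenness_raw).
    """
    nodes = list(graph.nodes())
    nb = {n: 0.0 for n in nodes}
    eb = {tuple(sorted(e)): 0.0 for e in graph.edges()}
    for i, s in enumerate(nodes):
        # BFS from s recording parents on shortest paths
        dist = {s: 0}
        parents = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parents[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    parents[v].append(u)
        for t in nodes[i + 1:]:
            if t not in dist or t == s:
                continue
            # enumerate all shortest s-t paths by backtracking
            paths = []

            def backtrack(node, acc):
                if node == s:
                    paths.append([s] + acc)
                    return
                for par in parents[node]:
                    backtrack(par, [node] + acc)

            backtrack(t, [])
            k = len(paths)
            for path in paths:
                for mid in path[1:-1]:
                    nb[mid] += 1.0 / k
                for a, b in zip(path, path[1:]):
                    eb[tuple(sorted((a, b)))] += 1.0 / k
    return nb, eb
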