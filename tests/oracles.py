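"""Independent brute-force oracles used to check the fast implementations.

Deliberately naive: dense matrices, exhaustive enumeration, no shared
code with the package's algorithm paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra


def dense_rwr(G: nx.Graph, seeds: set[str], damping: float, tol: float = 1e-14,
              max_iter: int = 100000) -> dict[str, float]:
    """Dense power iteration for random walk with restart on the gene graph."""
    nodes = sorted(G.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", 1.0))
        W[idx[u], idx[v]] = w
        W[idx[v], idx[u]] = w
    out = W.sum(axis=1)
    P = np.zeros((n, n))  # P[u, v] = transition prob u -> v
    for i in range(n):
        if out[i] > 0:
            P[i] = W[i] / out[i]
    dangling = out == 0
    r = np.zeros(n)
    for s in seeds:
        r[idx[s]] = 1.0 / len(seeds)
    p = r.copy()
    for _ in range(max_iter):
        p_next = (1 - damping) * r + damping * (P.T @ p + p[dangling].sum() * r)
        if np.abs(p_next - p).sum() <= tol:
            p = p_next
            break
        p = p_next
    return {v: float(p[idx[v]]) for v in nodes}


def degree_to_seeds_oracle(G: nx.Graph, seeds: set[str]) -> dict[str, float]:
    """Direct adjacency-list enumeration."""
    return {v: float(sum(1 for nb in G.neighbors(v) if nb in seeds)) for v in G.nodes}


def _dense_distances(G: nx.Graph) -> tuple[list[str], np.ndarray]:
    from scipy.sparse import csr_matrix

    nodes = sorted(G.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, data in G.edges(data=True):
        c = float(data.get("cost", 1.0))
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [c, c]
    D = csgraph_dijkstra(csr_matrix((vals, (rows, cols)), shape=(n, n)), directed=False)
    return nodes, D


def harmonic_to_seeds_oracle(G: nx.Graph, seeds: set[str]) -> dict[str, float]:
    """All-pairs shortest paths through scipy's csgraph Dijkstra."""
    nodes, D = _dense_distances(G)
    idx = {v: i for i, v in enumerate(nodes)}
    out = {}
    for v in nodes:
        total = 0.0
        for s in seeds:
            d = D[idx[v], idx[s]]
            if s != v and np.isfinite(d) and d > 0:
                total += 1.0 / d
        out[v] = total
    return out


def betweenness_among_seeds_oracle(G: nx.Graph, seeds: set[str]) -> dict[str, float]:
    """Exhaustive shortest-path enumeration per unordered seed pair."""
    scores = {v: 0.0 for v in G.nodes}
    for s, t in itertools.combinations(sorted(seeds), 2):
        if not nx.has_path(G, s, t):
            continue
        paths = list(nx.all_shortest_paths(G, s, t, weight="cost"))
        for v in G.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    return scores


def steiner_opt(G: nx.Graph, terminals: set[str]) -> float:
    """Exact minimum Steiner tree cost by exhaustive vertex-subset search."""
    others = sorted(set(G.nodes) - terminals)
    best = np.inf
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            nodes = terminals | set(extra)
            sub = G.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            mst = nx.minimum_spanning_tree(sub, weight="cost")
            cost = sum(float(d.get("cost", 1.0)) for _, _, d in mst.edges(data=True))
            best = min(best, cost)
    return float(best)


def kpm_opt(G: nx.Graph, seeds: set[str], k: int) -> int:
    """Exact best seed count over connected subgraphs with <= k exceptions.

    For any exception subset X, the best achievable solution is the
    richest-in-seeds connected component of G[S u X]; conversely every
    connected solution is contained in such a component.
    """
    non_seeds = sorted(set(G.nodes) - seeds)
    best = 0
    for r in range(k + 1):
        for X in itertools.combinations(non_seeds, r):
            sub = G.subgraph(seeds | set(X))
            for comp in nx.connected_components(sub):
                best = max(best, len(comp & seeds))
    return best
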