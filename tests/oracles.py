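"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit all-pairs BFS, explicit
enumeration of every shortest path, explicit enumeration of every query
subset for the hypergeometric tail.  None of it shares code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque

from mirnet_pd.network import RegulatoryNetwork


def net_from_edges(edges, name="test") -> RegulatoryNetwork:
    """Build a network from (mirna, gene) pairs."""
    net = RegulatoryNetwork(name=name)
    for m, g in edges:
        net.add_edge(m, g)
    return net


def random_bipartite(rng, max_side=4, p=0.5, connected=False):
    """Random bipartite graph with 1..max_side nodes per side (<= 8 total)."""
    while True:
        n_m = int(rng.integers(1, max_side + 1))
        n_g = int(rng.integers(1, max_side + 1))
        edges = [
            (f"m{i}", f"g{j}")
            for i in range(n_m)
            for j in range(n_g)
            if rng.random() < p
        ]
        if not edges:
            continue
        net = net_from_edges(edges)
        if not connected or len(net.components()) == 1:
            return net


def bfs_dist(net, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in net.adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def oracle_degree(net):
    return {v: sum(1 for _ in net.adj[v]) for v in net.nodes}


def oracle_closeness(net, within_component=False):
    n = net.n_nodes
    out = {}
    for v in net.nodes:
        dist = bfs_dist(net, v)
        total = sum(dist.values())
        if total == 0:
            out[v] = 0.0
        else:
            numer = (len(dist) - 1) if within_component else (n - 1)
            out[v] = numer / total
    return out


def _all_shortest_paths(net, s, t, dist_from_s):
    """Every shortest s→t path, by backward DFS over the BFS distances."""
    if t not in dist_from_s:
        return []
    paths = []

    def extend(path):
        head = path[-1]
        if head == s:
            paths.append(list(reversed(path)))
            return
        for u in net.adj[head]:
            if dist_from_s.get(u, -2) == dist_from_s[head] - 1:
                extend(path + [u])

    extend([t])
    return paths


def oracle_betweenness(net):
    """Sum over unordered pairs of the fraction of shortest paths through
    each interior node, by explicit path enumeration."""
    bc = {v: 0.0 for v in net.nodes}
    nodes = net.nodes
    for i, s in enumerate(nodes):
        dist = bfs_dist(net, s)
        for t in nodes[i + 1 :]:
            paths = _all_shortest_paths(net, s, t, dist)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def oracle_hypergeom_tail(k, K, n, N):
    """P(overlap >= k) by enumerating every size-n subset of an N-universe
    whose first K elements form the pathway."""
    pathway = set(range(K))
    hits = 0
    total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        hits += len(pathway.intersection(subset)) >= k
    return hits / total
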