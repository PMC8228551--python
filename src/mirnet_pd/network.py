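"""Bipartite miRNA–mRNA regulatory networks and their centrality analysis.

Networks are undirected simple bipartite graphs: miRNA nodes on one side,
target genes on the other, one edge per retained validated interaction.
Centralities follow the unnormalized conventions of the Cytoscape/CytoNCA
lineage commonly used for hub-gene ranking:

* degree (DC): raw integer edge count;
* betweenness (BC): Brandes shortest-path betweenness, each unordered pair
  counted once, endpoints excluded, no normalization;
* closeness (CC): (N − 1) / Σ_u d(v, u), the distance sum taken over the
  node's connected component and N the whole network's node count (so CC = 1
  only for a node adjacent to everything).

The betweenness implementation is the Brandes dependency-accumulation
algorithm; closeness and components come from plain breadth-first searches.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

import pandas as pd

from .targets import Interaction

logger = logging.getLogger(__name__)

NODE_KINDS = ("mirna", "gene")


@dataclass
class RegulatoryNetwork:
    """Undirected simple bipartite graph of miRNAs and genes."""

    name: str = ""
    kind: dict[str, str] = field(default_factory=dict)
    adj: dict[str, set[str]] = field(default_factory=dict)

    def add_edge(self, mirna: str, gene: str) -> None:
        if mirna == gene:
            raise ValueError(f"self-loop on {mirna!r}")
        if self.kind.get(mirna, "mirna") != "mirna":
            raise ValueError(f"{mirna!r} already present as a gene node")
        if self.kind.get(gene, "gene") != "gene":
            raise ValueError(f"{gene!r} already present as a miRNA node")
        self.kind[mirna] = "mirna"
        self.kind[gene] = "gene"
        self.adj.setdefault(mirna, set()).add(gene)
        self.adj.setdefault(gene, set()).add(mirna)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.kind)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Unordered edges, canonically (mirna, gene), sorted."""
        out = []
        for node, nbrs in self.adj.items():
            if self.kind[node] != "mirna":
                continue
            for g in nbrs:
                out.append((node, g))
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return len(self.kind)

    @property
    def n_edges(self) -> int:
        return sum(len(n) for n in self.adj.values()) // 2

    def neighbors(self, node: str) -> set[str]:
        return self.adj[node]

    def components(self) -> list[set[str]]:
        seen: set[str] = set()
        comps = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            queue = deque([start])
            while queue:
                v = queue.popleft()
                for w in self.adj.get(v, ()):
                    if w not in comp:
                        comp.add(w)
                        queue.append(w)
            seen |= comp
            comps.append(comp)
        return comps


def build_network(
    mirnas: Iterable[str],
    interactions: Sequence[Interaction],
    gene_universe: Iterable[str],
    name: str = "",
) -> RegulatoryNetwork:
    """Build the regulatory network of a miRNA set over a gene universe.

    Keeps every interaction whose miRNA is in ``mirnas`` and whose gene is in
    ``gene_universe``; nodes without a retained edge never enter the network.
    """
    mirnas = set(mirnas)
    universe = set(gene_universe)
    net = RegulatoryNetwork(name=name)
    for inter in interactions:
        if inter.mirna_id in mirnas and inter.gene in universe:
            net.add_edge(inter.mirna_id, inter.gene)
    if net.n_nodes == 0:
        logger.warning("network %r is empty", name)
    return net


def degree_centrality(net: RegulatoryNetwork) -> dict[str, int]:
    """Raw integer degree of every node."""
    return {v: len(net.adj.get(v, ())) for v in net.nodes}


def betweenness_centrality(net: RegulatoryNetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (Brandes accumulation).

    Each unordered node pair contributes once, with credit split equally
    across all of its shortest paths; endpoints receive no credit.
    """
    bc = {v: 0.0 for v in net.nodes}
    for s in net.nodes:
        # single-source shortest-path DAG
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in bc}
        sigma = {v: 0.0 for v in bc}
        dist = {v: -1 for v in bc}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in net.adj.get(v, ()):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation
        delta = {v: 0.0 for v in bc}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: x / 2.0 for v, x in bc.items()}


def _bfs_distances(net: RegulatoryNetwork, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in net.adj.get(v, ()):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def closeness_centrality(
    net: RegulatoryNetwork, within_component_norm: bool = False
) -> dict[str, float]:
    """Closeness (N − 1) / Σ d(v, u), the sum over v's component.

    With ``within_component_norm`` the numerator is the component size minus
    one instead of the whole network's N − 1.  Isolated-in-component nodes
    (distance sum 0) get closeness 0.
    """
    n = net.n_nodes
    cc = {}
    for v in net.nodes:
        dist = _bfs_distances(net, v)
        total = sum(dist.values())
        if total == 0:
            cc[v] = 0.0
        else:
            numer = (len(dist) - 1) if within_component_norm else (n - 1)
            cc[v] = numer / total
    return cc


def centrality_table(net: RegulatoryNetwork) -> pd.DataFrame:
    """All three centralities as a DataFrame (node_id, kind, dc, bc, cc)."""
    dc = degree_centrality(net)
    bc = betweenness_centrality(net)
    cc = closeness_centrality(net)
    return pd.DataFrame(
        {
            "node_id": net.nodes,
            "kind": [net.kind[v] for v in net.nodes],
            "dc": [dc[v] for v in net.nodes],
            "bc": [bc[v] for v in net.nodes],
            "cc": [cc[v] for v in net.nodes],
        }
    )


@dataclass(frozen=True)
class HubTable:
    """Top-k nodes under one centrality measure, deterministically ordered."""

    measure: str
    ranked: tuple[tuple[str, float], ...]


def rank_hubs(
    table: pd.DataFrame,
    measure: str,
    k: int,
    kind: str | None = None,
) -> HubTable:
    """Top-k nodes by ``measure`` (dc, bc or cc).

    Ties break deterministically: higher value first, then genes before
    miRNAs, then lexicographic node id.  ``kind`` restricts the ranking to
    one node class (e.g. genes only).  If k exceeds the candidate count all
    candidates are returned (logged).
    """
    if measure not in ("dc", "bc", "cc"):
        raise ValueError(f"unknown measure {measure!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = table
    if kind is not None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        rows = rows[rows["kind"] == kind]
    entries = sorted(
        rows.itertuples(index=False),
        key=lambda r: (-getattr(r, measure), r.kind != "gene", r.node_id),
    )
    if k > len(entries):
        logger.info("k=%d exceeds %d candidate nodes; returning all", k, len(entries))
    top = entries[:k]
    return HubTable(
        measure=measure,
        ranked=tuple((r.node_id, float(getattr(r, measure))) for r in top),
    )


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    n_mirna: int
    n_gene: int


def network_summary(net: RegulatoryNetwork) -> NetworkSummary:
    kinds = list(net.kind.values())
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        n_components=len(net.components()) if net.n_nodes else 0,
        n_mirna=kinds.count("mirna"),
        n_gene=kinds.count("gene"),
    )


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    """Three-column SIF export (mirna  targets  gene), sorted."""
    with open(path, "w") as fh:
        for mirna, gene in net.edges:
            fh.write(f"{mirna}\ttargets\t{gene}\n")


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    """Minimal GraphML export with a "kind" node attribute."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <key id="kind" for="node" attr.name="kind" attr.type="string"/>',
        '  <graph edgedefault="undirected">',
    ]
    for v in net.nodes:
        lines.append(
            f'    <node id="{escape(v, {chr(34): "&quot;"})}">'
            f'<data key="kind">{net.kind[v]}</data></node>'
        )
    for mirna, gene in net.edges:
        lines.append(
            f'    <edge source="{escape(mirna, {chr(34): "&quot;"})}"'
            f' target="{escape(gene, {chr(34): "&quot;"})}"/>'
        )
    lines += ["  </graph>", "</graphml>", ""]
    Path(path).write_text("\n".join(lines))


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.sort_values("node_id").copy()
    out["bc"] = out["bc"].map(lambda x: f"{x:.9g}")
    out["cc"] = out["cc"].map(lambda x: f"{x:.9g}")
    out.to_csv(path, sep="\t", index=False)
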