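"""Minimum spanning haplotype networks and the star-pattern statistic.

The MSN (epsilon = 0) is the union of all minimum spanning trees over the
pairwise mutation-step (Hamming) distances between haplotypes: processing
edge-weight classes in increasing order, every edge that joins two
components that were distinct before its weight class was processed is kept.
Edges are additionally flagged as present in *every* MST when they are
bridges of their weight-class subgraph (after contracting the components
already connected by lighter classes).

The star score quantifies the founder/bottleneck expansion signature — a
dominant central haplotype surrounded by rare satellites one or two
mutations away — as

    score = (frequency share of the modal haplotype)
            x (fraction of the remaining haplotypes within <= 2 mutations).

High scores indicate expansion; low scores the balanced, scattered pattern
characteristic of co-amplified pseudogene lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .seq_core import HaplotypeTable

__all__ = [
    "HaploNetwork",
    "pairwise_distance_matrix",
    "build_msn",
    "msn_from_table",
    "star_score",
]


def pairwise_distance_matrix(seqs: list[str]) -> np.ndarray:
    """Symmetric integer Hamming distances; a gap is a fifth state (any
    difference, gap included, counts one mutation step)."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 haplotypes")
    L = len(seqs[0])
    for s in seqs:
        if len(s) != L:
            raise ValueError("haplotype length mismatch")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return d.astype(int)


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


@dataclass
class HaploNetwork:
    """Frequency-weighted mutation-step graph with trait composition."""

    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def total_frequency(self) -> int:
        return sum(d.get("frequency", 0) for _, d in self.graph.nodes(data=True))

    def to_gml(self, path: str | Path) -> None:
        g = nx.Graph()
        for node, d in self.graph.nodes(data=True):
            attrs = {"frequency": int(d.get("frequency", 0))}
            for trait, cnt in sorted(d.get("traits", {}).items()):
                attrs[f"trait_{trait}"] = int(cnt)
            g.add_node(node, **attrs)
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]),
                       in_every_MST=int(d["in_every_MST"]))
        nx.write_gml(g, str(path))

    def to_nexus_network(self, path: str | Path, sequences: dict[str, str]) -> None:
        """PopART-flavoured nexus: taxa, a trait matrix and the edge list."""
        nodes = sorted(self.graph.nodes)
        traits = sorted({t for _, d in self.graph.nodes(data=True)
                         for t in d.get("traits", {})})
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(nodes)};\n  TAXLABELS\n")
            for n in nodes:
                fh.write(f"    {n}\n")
            fh.write("  ;\nEND;\n\nBEGIN TRAITS;\n")
            fh.write(f"  Dimensions NTRAITS={len(traits)};\n")
            fh.write("  Format labels=yes missing=? separator=Comma;\n")
            fh.write(f"  TraitLabels {' '.join(traits)};\n  Matrix\n")
            for n in nodes:
                d = self.graph.nodes[n].get("traits", {})
                fh.write(f"    {n} {','.join(str(d.get(t, 0)) for t in traits)}\n")
            fh.write("  ;\nEND;\n\nBEGIN NETWORK;\n  EDGES\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"    {u} -- {v} : {d['weight']}\n")
            fh.write("  ;\nEND;\n")


def build_msn(
    dist: np.ndarray,
    labels: list[str] | None = None,
    epsilon: int = 0,
) -> HaploNetwork:
    """Union of all minimum spanning trees over a distance matrix.

    Kruskal over weight classes: within each class, every edge joining
    components that were distinct before the class was processed is added;
    an edge is in every MST iff it is a bridge of the class subgraph on the
    contracted components.
    """
    if epsilon != 0:
        raise NotImplementedError("only the strict MSN (epsilon=0) is supported")
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if labels is None:
        labels = [f"Hap{i + 1}" for i in range(n)]

    g = nx.Graph()
    g.add_nodes_from(labels)
    dsu = _DSU(n)
    weights = sorted({int(dist[i, j]) for i in range(n) for j in range(i + 1, n)})
    for w in weights:
        if w <= 0:
            raise ValueError("distinct haplotypes must differ (weight >= 1)")
        class_edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if int(dist[i, j]) == w and dsu.find(i) != dsu.find(j)
        ]
        if not class_edges:
            continue
        # contracted class subgraph: components (as of before this class)
        # joined by this class's edges; parallel edges kill bridge status
        contracted = nx.MultiGraph()
        for i, j in class_edges:
            contracted.add_edge(dsu.find(i), dsu.find(j), orig=(i, j))
        simple = nx.Graph(contracted)
        multi = {
            (u, v)
            for u, v in simple.edges
            if contracted.number_of_edges(u, v) > 1
        }
        bridges = {
            frozenset(e) for e in nx.bridges(simple)
            if frozenset(e) not in {frozenset(m) for m in multi}
        }
        for i, j in class_edges:
            key = frozenset((dsu.find(i), dsu.find(j)))
            g.add_edge(
                labels[i], labels[j], weight=w,
                in_every_MST=key in bridges, in_some_MST=True,
            )
        for i, j in class_edges:
            dsu.union(i, j)
    return HaploNetwork(g)


def msn_from_table(table: HaplotypeTable) -> HaploNetwork:
    """MSN over a haplotype table, annotated with frequencies and per-farm
    trait composition."""
    labels = [h.id for h in table.haplotypes]
    if len(labels) == 1:
        g = nx.Graph()
        h = table.haplotypes[0]
        g.add_node(h.id, frequency=h.total, traits=dict(h.counts))
        return HaploNetwork(g)
    dist = pairwise_distance_matrix([h.sequence for h in table.haplotypes])
    net = build_msn(dist, labels)
    for h in table.haplotypes:
        net.graph.nodes[h.id]["frequency"] = h.total
        net.graph.nodes[h.id]["traits"] = dict(h.counts)
    return net


def star_score(
    table: HaplotypeTable,
    population: str,
    max_satellite_distance: int = 2,
) -> tuple[float, str]:
    """Star-pattern score for one population; returns (score, hub id).

    A single-haplotype population scores 1.0 by convention (a degenerate
    star)."""
    haps = [h for h in table.haplotypes if h.counts.get(population, 0) > 0]
    if not haps:
        raise ValueError(f"population {population!r} not present")
    counts = {h.id: h.counts[population] for h in haps}
    total = sum(counts.values())
    hub = min(counts, key=lambda k: (-counts[k], k))
    if len(haps) == 1:
        return 1.0, hub
    hub_seq = next(h.sequence for h in haps if h.id == hub)
    others = [h for h in haps if h.id != hub]
    close = sum(
        1
        for h in others
        if sum(x != y for x, y in zip(h.sequence, hub_seq)) <= max_satellite_distance
    )
    score = (counts[hub] / total) * (close / len(others))
    return score, hub
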