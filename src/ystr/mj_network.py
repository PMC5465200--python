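"""Median-joining networks over STR haplotypes and descent-cluster calling.

The network is built on distinct 15-locus profiles under the L1 (step)
metric.  Candidate links are the epsilon-relaxed minimum-spanning-network
edges: a pair is linked when its distance does not exceed the bottleneck
(minimax-path) distance between the two profiles plus epsilon.  For every
pair of links sharing a node, the per-locus median of the three profiles is
proposed; medians are added one at a time whenever they lower the spanning
cost of the node set, to a fixpoint, after which median vectors that end up
with fewer than two links are pruned.  All tie-breaking is lexicographic on
allele vectors, so the result is independent of input order.

Cluster delineation follows a zone -> ancestor -> clade procedure: grow a
connected zone around the founder while the fraction of its samples coming
from the seed population stays at or above the enrichment threshold, then
attribute to the cluster every sample whose node's shortest path to the
founder stays inside the zone, excluding nodes beyond a distance cap.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from ystr.data_io import STR_LOCI_15, StrHaplotype
from ystr.str_clusters import ModalHaplotype

Profile = tuple[int, ...]


def _l1(u: Profile, v: Profile) -> int:
    return sum(abs(a - b) for a, b in zip(u, v))


def _distance_matrix(nodes: Sequence[Profile]) -> np.ndarray:
    arr = np.asarray(nodes, dtype=int)
    return np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=2)


def _mst(nodes: Sequence[Profile]) -> tuple[float, list[tuple[int, int]]]:
    """Total minimum-spanning-tree cost and its edge list (index pairs)."""
    d = _distance_matrix(nodes)
    t = minimum_spanning_tree(d).tocoo()
    edges = list(zip(t.row.tolist(), t.col.tolist()))
    return float(t.sum()), edges


def spanning_cost(nodes: Sequence[Profile]) -> float:
    """Minimum cost of connecting all profiles (MST over the node set)."""
    if len(nodes) < 2:
        return 0.0
    return _mst(nodes)[0]


def _bottleneck(nodes: Sequence[Profile]) -> np.ndarray:
    """Minimax path weight between all node pairs, via the MST."""
    n = len(nodes)
    d = _distance_matrix(nodes)
    _, edges = _mst(nodes)
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for i, j in edges:
        w = int(d[i, j])
        adj[i].append((j, w))
        adj[j].append((i, w))
    bn = np.zeros((n, n), dtype=int)
    for src in range(n):
        # DFS over the tree carrying the max edge weight seen so far
        stack = [(src, -1, 0)]
        while stack:
            node, parent, mx = stack.pop()
            bn[src, node] = mx
            for nb, w in adj[node]:
                if nb != parent:
                    stack.append((nb, node, max(mx, w)))
    return bn


def _feasible_links(nodes: Sequence[Profile], epsilon: int) -> list[tuple[int, int]]:
    if len(nodes) < 2:
        return []
    d = _distance_matrix(nodes)
    bn = _bottleneck(nodes)
    n = len(nodes)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= bn[i, j] + epsilon
    ]


def _median_profile(u: Profile, v: Profile, w: Profile) -> Profile:
    return tuple(sorted(t)[1] for t in zip(u, v, w))


@dataclass
class MedianNetwork:
    """Observed + inferred median profiles with mutation-labelled links."""

    haplogroup: str
    epsilon: int
    nodes: list[Profile]  # lexicographically sorted
    kinds: dict[Profile, str]  # observed | median
    carriers: dict[Profile, list[StrHaplotype]] = field(default_factory=dict)
    populations: dict[Profile, Counter] = field(default_factory=dict)
    edges: list[tuple[Profile, Profile]] = field(default_factory=list)

    def multiplicity(self, node: Profile) -> int:
        return len(self.carriers.get(node, []))

    def neighbors(self, node: Profile) -> list[Profile]:
        out = []
        for u, v in self.edges:
            if u == node:
                out.append(v)
            elif v == node:
                out.append(u)
        return sorted(out)

    def total_cost(self) -> float:
        """Spanning cost of the final node set (medians included)."""
        return spanning_cost(self.nodes)

    def to_graph(self) -> nx.Graph:
        """GraphML-ready graph: node attrs kind/multiplicity/populations,
        edge attrs weight and the list of mutated loci."""
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                ",".join(map(str, node)),
                kind=self.kinds[node],
                multiplicity=self.multiplicity(node),
                populations=";".join(
                    f"{p}:{c}" for p, c in sorted(
                        self.populations.get(node, Counter()).items()
                    )
                ),
            )
        for u, v in self.edges:
            changes = [
                f"{STR_LOCI_15[i]}:{v[i] - u[i]:+d}"
                for i in range(len(u)) if u[i] != v[i]
            ]
            g.add_edge(
                ",".join(map(str, u)),
                ",".join(map(str, v)),
                weight=_l1(u, v),
                loci=";".join(changes),
            )
        return g


@dataclass
class DescentCluster:
    """Samples attributed to a founder's clade on the network (N***)."""

    name: str
    founder: ModalHaplotype
    members: list[StrHaplotype]
    member_nodes: list[Profile]
    seed_population: str
    enrichment: float
    empty: bool = False

    @property
    def n(self) -> int:
        return len(self.members)


def build_network(
    haplotypes: Sequence[StrHaplotype],
    populations: Optional[Sequence[str]] = None,
    epsilon: int = 0,
) -> MedianNetwork:
    """Median-joining network of a single haplogroup's haplotypes.

    ``populations`` optionally labels each input haplotype's source
    population (parallel list) for later cluster delineation.
    """
    if not haplotypes:
        raise ValueError("no haplotypes")
    haplogroups = {h.haplogroup for h in haplotypes}
    if len(haplogroups) > 1:
        raise ValueError(f"mixed haplogroups in network input: {haplogroups}")
    if populations is not None and len(populations) != len(haplotypes):
        raise ValueError("populations list must parallel haplotypes")

    carriers: dict[Profile, list[StrHaplotype]] = {}
    pop_comp: dict[Profile, Counter] = {}
    for idx, h in enumerate(haplotypes):
        carriers.setdefault(h.alleles, []).append(h)
        pop_comp.setdefault(h.alleles, Counter())
        if populations is not None:
            pop_comp[h.alleles][populations[idx]] += 1
    observed = sorted(carriers)
    if len(observed) < 2:
        raise ValueError("need at least two distinct profiles")

    nodes: list[Profile] = list(observed)
    node_set = set(nodes)
    while True:
        links = _feasible_links(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in links:
            adj[i].add(j)
            adj[j].add(i)
        cur_cost = spanning_cost(nodes)
        candidates: set[Profile] = set()
        for center, nbrs in adj.items():
            nbrs = sorted(nbrs)
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    m = _median_profile(
                        nodes[center], nodes[nbrs[a]], nodes[nbrs[b]]
                    )
                    if m not in node_set:
                        candidates.add(m)
        best: Optional[tuple[float, Profile]] = None
        for m in sorted(candidates):
            new_cost = spanning_cost(nodes + [m])
            if new_cost < cur_cost and (best is None or
                                        (new_cost, m) < best):
                best = (new_cost, m)
        if best is None:
            break
        nodes.append(best[1])
        node_set.add(best[1])
        nodes.sort()

    # prune median vectors that end up with fewer than two links
    while True:
        links = _feasible_links(nodes, epsilon)
        degree = Counter()
        for i, j in links:
            degree[i] += 1
            degree[j] += 1
        drop = [
            nodes[i] for i in range(len(nodes))
            if nodes[i] not in carriers and degree[i] < 2
        ]
        if not drop:
            break
        nodes = [v for v in nodes if v not in set(drop)]

    links = _feasible_links(nodes, epsilon)
    edges = sorted((min(nodes[i], nodes[j]), max(nodes[i], nodes[j]))
                   for i, j in links)
    return MedianNetwork(
        haplogroup=next(iter(haplogroups)),
        epsilon=epsilon,
        nodes=list(nodes),
        kinds={v: ("observed" if v in carriers else "median") for v in nodes},
        carriers=carriers,
        populations=pop_comp,
        edges=edges,
    )


def _shortest_paths(
    net: MedianNetwork, source: Profile
) -> dict[Profile, tuple[float, tuple[Profile, ...]]]:
    """Deterministic Dijkstra: ties broken toward the lexicographically
    smallest node path after cost."""
    adj: dict[Profile, list[tuple[Profile, int]]] = {v: [] for v in net.nodes}
    for u, v in net.edges:
        w = _l1(u, v)
        adj[u].append((v, w))
        adj[v].append((u, w))
    best: dict[Profile, tuple[float, tuple[Profile, ...]]] = {}
    heap: list[tuple[float, tuple[Profile, ...]]] = [(0.0, (source,))]
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (dist, path)
        for nb, w in adj[node]:
            if nb not in best:
                heapq.heappush(heap, (dist + w, path + (nb,)))
    return best


def delineate_cluster(
    net: MedianNetwork,
    seed_population: str,
    founder: ModalHaplotype,
    enrichment_threshold: float = 0.5,
    distance_cap: int = 4,
    name: str = "cluster",
) -> DescentCluster:
    """Zone -> founder-rooted clade attribution of samples to a cluster.

    The zone grows greedily from the founder node, at each step adding the
    adjacent node that best preserves seed-population enrichment, while the
    running fraction of zone samples from ``seed_population`` stays at or
    above the threshold.  Median nodes carry no samples and pass through
    freely.  A node's samples join the cluster when its shortest path to the
    founder lies inside the zone and its distance is within ``distance_cap``.
    """
    fnode = founder.haplotype.alleles
    if fnode not in set(net.nodes):
        raise ValueError("founder profile absent from network")

    def seed_count(v: Profile) -> int:
        return net.populations.get(v, Counter()).get(seed_population, 0)

    def total_count(v: Profile) -> int:
        return net.multiplicity(v)

    zone = {fnode}
    seed_n, tot_n = seed_count(fnode), total_count(fnode)
    if tot_n > 0 and seed_n / tot_n < enrichment_threshold:
        return DescentCluster(
            name=name, founder=founder, members=[], member_nodes=[],
            seed_population=seed_population, enrichment=0.0, empty=True,
        )
    while True:
        frontier = sorted(
            {nb for v in zone for nb in net.neighbors(v)} - zone
        )
        admissible = []
        for v in frontier:
            s, t = seed_n + seed_count(v), tot_n + total_count(v)
            if t == 0 or s / t >= enrichment_threshold:
                admissible.append(v)
        if not admissible:
            break
        admissible.sort(
            key=lambda v: (-(seed_count(v)),
                           total_count(v) - seed_count(v), v)
        )
        v = admissible[0]
        zone.add(v)
        seed_n += seed_count(v)
        tot_n += total_count(v)

    paths = _shortest_paths(net, fnode)
    member_nodes = []
    for v in sorted(zone):
        if v not in paths:
            continue
        dist, path = paths[v]
        if dist <= distance_cap and all(p in zone for p in path):
            member_nodes.append(v)
    members = [h for v in member_nodes for h in net.carriers.get(v, [])]
    enrichment = (seed_n / tot_n) if tot_n else 0.0
    return DescentCluster(
        name=name,
        founder=founder,
        members=members,
        member_nodes=member_nodes,
        seed_population=seed_population,
        enrichment=enrichment,
        empty=len(members) == 0,
    )
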