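"""Protein complex detection by weighted seeded cluster expansion.

Vertices are weighted by the sum of their incident edge scores and queued in
non-increasing weight order (ties by degree, then ID). The head of the queue
seeds a cluster K that grows greedily: among neighbors v of K satisfying

    E_vk = e_vk / w_k >= T_in     and    diameter(K + v) <= d

(e_vk = total edge weight between v and K, w_k = total edge weight inside K,
diameter in unweighted hops on the induced subgraph) the one with the
largest E_vk is admitted (ties: higher vertex weight, then ID), and all
E_vk are recomputed. A singleton seed has w_k = 0; its best-connected
neighbor is admitted unconditionally (E_vk = +inf) unless the
skip-singleton-seed mode is on. Emitted clusters are deduplicated and
filtered by minimum size. Members leave the seed queue but, with overlap
allowed (the default), remain eligible to join later clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .io_formats import ComplexSet


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]
    weight: float  # total edge weight inside the cluster (w_k)
    seed: str
    admissions: tuple[tuple[str, float], ...]  # (vertex, E_vk at admission)


def vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """weight(v) = sum of incident edge weights; isolated vertices get 0."""
    return {
        v: sum(d.get("weight", 1.0) for _, _, d in graph.edges(v, data=True))
        for v in graph.nodes
    }


def build_seed_queue(weights: Mapping[str, float],
                     degrees: Mapping[str, int]) -> list[str]:
    """Vertices in non-increasing weight order; ties by non-increasing
    degree, then lexicographic ID."""
    if set(weights) != set(degrees):
        raise ValueError("weights and degrees must cover the same vertices")
    return sorted(weights, key=lambda v: (-weights[v], -degrees[v], v))


def interaction_probability(v: str, K: Iterable[str], graph: nx.Graph) -> float:
    """E_vk = e_vk / w_k; +inf sentinel when the cluster has no internal
    weight (singleton seed bootstrap), 0 when v has no edge into K."""
    members = set(K)
    if v in members:
        raise ValueError(f"vertex {v!r} is already in the cluster")
    adj = graph[v] if v in graph else {}
    e_vk = sum(d.get("weight", 1.0) for u, d in adj.items() if u in members)
    w_k = sum(d.get("weight", 1.0)
              for a, b, d in graph.subgraph(members).edges(data=True))
    if w_k == 0.0:
        return math.inf if e_vk > 0.0 else 0.0
    return e_vk / w_k


def _diameter_ok(graph: nx.Graph, members: set[str], d: int) -> bool:
    """True iff the induced subgraph is connected with diameter <= d hops."""
    sub = graph.subgraph(members)
    n = len(members)
    for source in members:
        lengths = nx.single_source_shortest_path_length(sub, source, cutoff=d)
        if len(lengths) < n:
            return False
    return True


def expand_cluster(seed: str, graph: nx.Graph, T_in: float = 0.6, d: int = 2,
                   weights: Mapping[str, float] | None = None,
                   skip_singleton_seed: bool = False) -> Cluster:
    """Grow a cluster from ``seed`` until no neighbor qualifies."""
    if seed not in graph:
        raise ValueError(f"seed {seed!r} not in network")
    if weights is None:
        weights = vertex_weights(graph)
    K: set[str] = {seed}
    w_k = 0.0
    admissions: list[tuple[str, float]] = []
    while True:
        if w_k == 0.0 and skip_singleton_seed and len(K) == 1:
            break
        # e_vk per frontier vertex, computed incrementally
        e_into: dict[str, float] = {}
        for u in K:
            for v, data in graph[u].items():
                if v not in K:
                    e_into[v] = e_into.get(v, 0.0) + data.get("weight", 1.0)
        best: tuple[float, float, str] | None = None
        best_v: str | None = None
        for v, e_vk in e_into.items():
            E = math.inf if w_k == 0.0 else e_vk / w_k
            if E < T_in:
                continue
            if not _diameter_ok(graph, K | {v}, d):
                continue
            key = (E, weights.get(v, 0.0), v)
            # maximize E, then vertex weight; minimize ID on full ties
            if best is None or (key[0], key[1], _NegStr(key[2])) > (
                    best[0], best[1], _NegStr(best[2])):
                best = key
                best_v = v
        if best_v is None:
            break
        K.add(best_v)
        w_k += e_into[best_v]
        admissions.append((best_v, best[0]))
    return Cluster(members=frozenset(K), weight=w_k, seed=seed,
                   admissions=tuple(admissions))


class _NegStr:
    """Inverts string comparison so max() prefers the smaller ID."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_NegStr") -> bool:
        return self.s < other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


def detect_clusters(graph: nx.Graph, T_in: float = 0.6, d: int = 2,
                    min_complex_size: int = 3, allow_overlap: bool = True,
                    skip_singleton_seed: bool = False) -> list[Cluster]:
    """Seed from the weight queue, expand, remove members from the queue;
    returns kept clusters in seed order (duplicates by membership dropped)."""
    weights = vertex_weights(graph)
    degrees = dict(graph.degree())
    queue = build_seed_queue(weights, degrees)
    in_queue = set(queue)
    work = graph.copy() if not allow_overlap else graph
    kept: list[Cluster] = []
    seen: set[frozenset[str]] = set()
    for v in queue:
        if v not in in_queue:
            continue
        if not allow_overlap and v not in work:
            in_queue.discard(v)
            continue
        cluster = expand_cluster(v, work, T_in=T_in, d=d, weights=weights,
                                 skip_singleton_seed=skip_singleton_seed)
        in_queue -= cluster.members
        if not allow_overlap:
            work.remove_nodes_from(cluster.members & set(work.nodes))
        if len(cluster.members) >= min_complex_size and cluster.members not in seen:
            seen.add(cluster.members)
            kept.append(cluster)
    return kept


def detect_complexes(graph: nx.Graph, T_in: float = 0.6, d: int = 2,
                     min_complex_size: int = 3, allow_overlap: bool = True,
                     skip_singleton_seed: bool = False) -> ComplexSet:
    clusters = detect_clusters(graph, T_in=T_in, d=d,
                               min_complex_size=min_complex_size,
                               allow_overlap=allow_overlap,
                               skip_singleton_seed=skip_singleton_seed)
    return ComplexSet(tuple(c.members for c in clusters))
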