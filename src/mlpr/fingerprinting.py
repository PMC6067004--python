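"""Fingerprint collapsing and the top-T fingerprint similarity network.

Protein pairs whose (quantized) evidence vectors are identical share a
fingerprint; the random walk then operates on fingerprints rather than on
individual pairs. Fingerprints are linked to their T nearest fingerprints by
Euclidean distance, the directed kNN relation is symmetrized by union, and
edge weights follow the min-max rescaled similarity
M_ij = 1 - (dist - dmin) / (dmax - dmin) with dmin/dmax taken globally over
all distances realized during construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .io_formats import Pair
from .pair_features import N_COMPONENTS, PairVector

logger = logging.getLogger(__name__)


def quantize_vector(v: Iterable[float], precision: int = 4) -> tuple[float, ...]:
    """Round each component half-to-even to `precision` decimals.

    The resulting tuple is the hashable key that defines vector identity.
    """
    if precision < 0:
        raise ValueError("precision must be >= 0")
    key = []
    for x in v:
        x = float(x)
        if not math.isfinite(x):
            raise ValueError(f"non-finite vector component {x!r}")
        key.append(round(x, precision) + 0.0)  # normalize -0.0
    return tuple(key)


@dataclass(frozen=True)
class FingerprintTable:
    """Partition of pairs into identical-vector classes.

    Fingerprint IDs are 0..F-1 in lexicographic order of quantized vectors;
    ``members[fid]`` lists the pairs mapped to fingerprint ``fid``.
    """

    keys: tuple[tuple[float, ...], ...]
    members: tuple[tuple[Pair, ...], ...]

    @property
    def n_fingerprints(self) -> int:
        return len(self.keys)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(m) for m in self.members)

    @property
    def n_pairs(self) -> int:
        return sum(self.counts)

    @property
    def vectors(self) -> np.ndarray:
        """Representative (quantized) vectors as an F x 17 array."""
        if not self.keys:
            return np.zeros((0, N_COMPONENTS))
        return np.asarray(self.keys, dtype=float)

    def pair_to_fid(self) -> dict[Pair, int]:
        return {p: fid for fid, pairs in enumerate(self.members) for p in pairs}


def assign_fingerprints(items: Iterable[tuple[Pair, PairVector]],
                        precision: int = 4) -> FingerprintTable:
    """Group (pair, vector) records by quantized vector identity."""
    groups: dict[tuple[float, ...], list[Pair]] = {}
    seen: set[Pair] = set()
    for pair, vec in items:
        if pair in seen:
            raise ValueError(f"duplicate pair {pair!r}")
        seen.add(pair)
        groups.setdefault(quantize_vector(vec, precision), []).append(pair)
    keys = tuple(sorted(groups))
    members = tuple(tuple(sorted(groups[k])) for k in keys)
    return FingerprintTable(keys=keys, members=members)


def eq1_similarity(dist: float, dmin: float, dmax: float) -> float:
    """Min-max rescaled similarity; 1 at dmin, 0 at dmax.

    When dmax == dmin the network is degenerate and every edge gets 1.
    """
    eps = 1e-12 * max(1.0, abs(dmax))
    if dist < dmin - eps or dist > dmax + eps:
        raise ValueError(f"dist {dist} outside [{dmin}, {dmax}]")
    if dmax == dmin:
        return 1.0
    return 1.0 - (min(max(dist, dmin), dmax) - dmin) / (dmax - dmin)


@dataclass(frozen=True)
class SimilarityGraph:
    """Union-symmetrized top-T fingerprint graph and its transition matrix."""

    n: int
    edges: tuple[tuple[int, int, float, float], ...]  # (i, j, dist, weight), i < j
    adjacency: sp.csr_matrix
    transition: sp.csr_matrix
    dmin: float
    dmax: float


def build_knn_graph(table: FingerprintTable, T: int,
                    block_size: int = 2048) -> SimilarityGraph:
    """Exact top-T neighbor graph by blocked brute-force distances.

    Ties at the T-th neighbor distance are broken by smaller fingerprint ID.
    dmin/dmax for the edge weights are global over all pairwise distances
    evaluated. The transition matrix is the row-normalized weighted
    adjacency; rows whose incident weights are all zero stay zero.
    """
    F = table.n_fingerprints
    if F < 2:
        raise ValueError(f"need at least 2 fingerprints, got {F}")
    if T < 1:
        raise ValueError("T must be >= 1")
    X = table.vectors
    k = min(T, F - 1)
    edge_dist: dict[tuple[int, int], float] = {}
    dmin, dmax = math.inf, -math.inf
    for start in range(0, F, block_size):
        stop = min(start + block_size, F)
        D = cdist(X[start:stop], X)
        rows = np.arange(start, stop)
        D[rows - start, rows] = np.nan  # mask self-distances
        blk_min = np.nanmin(D)
        blk_max = np.nanmax(D)
        dmin = min(dmin, float(blk_min))
        dmax = max(dmax, float(blk_max))
        D[rows - start, rows] = np.inf
        for r, i in enumerate(rows):
            row = D[r]
            part = np.argpartition(row, k - 1)[:k]
            tie_val = row[part].max()
            cand = np.nonzero(row <= tie_val)[0]
            order = cand[np.lexsort((cand, row[cand]))][:k]
            for j in order:
                key = (i, int(j)) if i < j else (int(j), i)
                edge_dist[key] = float(row[j])
    edges = tuple(
        (i, j, d, eq1_similarity(d, dmin, dmax))
        for (i, j), d in sorted(edge_dist.items())
    )
    if edges:
        ii = np.fromiter((e[0] for e in edges), dtype=np.int64, count=len(edges))
        jj = np.fromiter((e[1] for e in edges), dtype=np.int64, count=len(edges))
        ww = np.fromiter((e[3] for e in edges), dtype=float, count=len(edges))
        adjacency = sp.coo_matrix(
            (np.concatenate([ww, ww]),
             (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(F, F),
        ).tocsr()
    else:  # pragma: no cover - unreachable for F >= 2, T >= 1
        adjacency = sp.csr_matrix((F, F))
    row_sums = np.asarray(adjacency.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    transition = sp.diags(inv) @ adjacency
    n_zero = int((row_sums == 0).sum())
    if n_zero:
        logger.warning("%d fingerprint(s) have zero incident weight; their "
                       "transition rows are zero", n_zero)
    return SimilarityGraph(n=F, edges=edges, adjacency=adjacency,
                           transition=transition.tocsr(), dmin=dmin, dmax=dmax)
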