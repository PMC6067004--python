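"""Seed priors, random walk with restart, and ranked network reconstruction.

Fingerprints whose vectors show membership in at least two curated PPI
databases and have more than half of all components non-zero are the walk's
seeds. Starting from the seed prior F0, the walk iterates

    F_r = (1 - alpha) * M @ F_{r-1} + alpha * F0        (F_1 = F0)

on the row-normalized fingerprint-similarity matrix M until the L1 step
difference drops below the tolerance. Every protein pair inherits its
fingerprint's posterior as a reliability score; the top-ranked pairs become
the edges of the reconstructed weighted network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .fingerprinting import FingerprintTable
from .io_formats import Pair
from .pair_features import PAIR_COMPONENTS

DEFAULT_SEED_INDICATORS = ("EPPI1", "EPPI2", "TAP1", "TAP5")

_COMPONENT_INDEX = {name: i for i, name in enumerate(PAIR_COMPONENTS)}


class ConvergenceError(RuntimeError):
    """Raised when the walk fails to reach the tolerance within max_iter."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def is_reliable_seed(vector: Sequence[float],
                     indicators: Sequence[str] = DEFAULT_SEED_INDICATORS,
                     min_indicators: int = 2) -> bool:
    """Seed rule: >= `min_indicators` non-zero database-membership
    components AND strictly more than half of all components non-zero."""
    idx = [_COMPONENT_INDEX[name] for name in indicators]
    n_db = sum(1 for i in idx if vector[i] != 0)
    n_nonzero = sum(1 for x in vector if x != 0)
    return n_db >= min_indicators and n_nonzero > len(vector) / 2


def seed_priors(table: FingerprintTable,
                indicators: Sequence[str] = DEFAULT_SEED_INDICATORS,
                min_indicators: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Prior vector F0 with equal mass 1/|seeds| on seed fingerprints.

    Returns (F0, seed_ids). The walk is linear in F0, so the normalization
    constant never changes the ranking.
    """
    seeds = np.array(
        [fid for fid, key in enumerate(table.keys)
         if is_reliable_seed(key, indicators, min_indicators)],
        dtype=np.int64,
    )
    if seeds.size == 0:
        raise ValueError(
            "no fingerprint satisfies the seed rule; relax the indicator set "
            "or the membership threshold"
        )
    f0 = np.zeros(table.n_fingerprints)
    f0[seeds] = 1.0 / seeds.size
    return f0, seeds


@dataclass(frozen=True)
class RWRResult:
    posterior: np.ndarray
    n_iter: int
    last_diff: float
    residual: float


def random_walk_with_restart(M, f0: np.ndarray, alpha: float = 0.8,
                             tol: float = 1e-6,
                             max_iter: int = 10_000) -> RWRResult:
    """Iterate the restart walk to its steady state.

    ``M`` is the row-normalized (row-stochastic) adjacency, dense or sparse.
    Stops when the L1 difference between successive iterates falls below
    ``tol``; the returned vector's fixed-point residual
    ||F - (1-alpha) M F - alpha F0||_1 is checked to be < 10 * tol.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    f0 = np.asarray(f0, dtype=float)
    f = f0.copy()
    diff = np.inf
    for r in range(2, max_iter + 2):
        f_next = (1.0 - alpha) * (M @ f) + alpha * f0
        diff = float(np.abs(f_next - f).sum())
        f = f_next
        if diff < tol:
            residual = float(np.abs(f - (1.0 - alpha) * (M @ f) - alpha * f0).sum())
            if residual >= 10.0 * tol:
                raise ConvergenceError(
                    f"fixed-point residual {residual:.3e} exceeds 10*tol", residual)
            return RWRResult(posterior=f, n_iter=r - 1, last_diff=diff,
                             residual=residual)
    residual = float(np.abs(f - (1.0 - alpha) * (M @ f) - alpha * f0).sum())
    raise ConvergenceError(
        f"no convergence within {max_iter} iterations (last diff {diff:.3e})",
        residual)


def score_and_rank_pairs(posterior: np.ndarray,
                         table: FingerprintTable) -> list[tuple[Pair, float]]:
    """Each pair inherits its fingerprint's posterior; sort descending,
    ties broken by canonical pair identity."""
    if len(posterior) != table.n_fingerprints:
        raise ValueError("posterior length does not match fingerprint count")
    ranked = [(pair, float(posterior[fid]))
              for fid, pairs in enumerate(table.members) for pair in pairs]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


@dataclass(frozen=True)
class ReconstructedNetwork:
    """Ranked, score-weighted protein edge list (scores non-increasing)."""

    edges: tuple[tuple[str, str, float], ...]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def pairs(self) -> tuple[Pair, ...]:
        return tuple((a, b) for a, b, _ in self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g


def select_top(ranked: list[tuple[Pair, float]],
               top_n: int | None) -> ReconstructedNetwork:
    """Keep the first ``top_n`` ranked pairs as weighted edges (all if None)."""
    if top_n is not None:
        if top_n < 0:
            raise ValueError("top_n must be >= 0")
        ranked = ranked[:top_n]
    return ReconstructedNetwork(tuple((a, b, s) for (a, b), s in ranked))
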