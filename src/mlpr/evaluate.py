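"""Benchmark scoring of predicted complexes and functional enrichment.

A predicted complex p matches a benchmark complex b when their neighborhood
affinity NA(p, b) = |p & b|^2 / (|p| * |b|) reaches the threshold omega.
Precision = Ncp / |P| and recall = Ncb / |B| count matched predicted and
benchmark complexes; the F-value is their harmonic mean. Functional
homogeneity is the smallest hypergeometric upper-tail p-value of a cluster
over all annotation groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .io_formats import Pair, canonical_pair

logger = logging.getLogger(__name__)


def na_score(p: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Neighborhood affinity |p & b|^2 / (|p| * |b|); symmetric, in [0, 1]."""
    if not p or not b:
        raise ValueError("NA score undefined for empty protein sets")
    inter = len(set(p) & set(b))
    return inter * inter / (len(p) * len(b))


def match_counts(P: Iterable[frozenset[str]], B: Iterable[frozenset[str]],
                 omega: float = 0.25) -> tuple[int, int]:
    """(Ncp, Ncb): predicted complexes matching >=1 benchmark complex at
    NA >= omega, and vice versa."""
    if not (0.0 < omega <= 1.0):
        raise ValueError(f"omega must be in (0, 1], got {omega}")
    P, B = list(P), list(B)
    matched_p = [False] * len(P)
    matched_b = [False] * len(B)
    for i, p in enumerate(P):
        for j, b in enumerate(B):
            if (not matched_p[i] or not matched_b[j]) and na_score(p, b) >= omega:
                matched_p[i] = True
                matched_b[j] = True
    return sum(matched_p), sum(matched_b)


@dataclass(frozen=True)
class EvalSummary:
    n_pred: int
    n_bench: int
    ncp: int
    ncb: int
    precision: float
    recall: float
    f_value: float
    omega: float


def precision_recall_f(P: Iterable[frozenset[str]], B: Iterable[frozenset[str]],
                       omega: float = 0.25) -> EvalSummary:
    """Eqs.-style precision/recall/F at threshold omega.

    An empty prediction set yields (0, 0, 0) so parameter sweeps never
    crash; an empty benchmark is an error.
    """
    P, B = list(P), list(B)
    if not B:
        raise ValueError("benchmark complex set must be non-empty")
    if not P:
        return EvalSummary(0, len(B), 0, 0, 0.0, 0.0, 0.0, omega)
    ncp, ncb = match_counts(P, B, omega)
    precision = ncp / len(P)
    recall = ncb / len(B)
    denom = precision + recall
    f_value = 0.0 if denom == 0.0 else 2.0 * precision * recall / denom
    return EvalSummary(len(P), len(B), ncp, ncb, precision, recall, f_value, omega)


def hypergeom_pvalues(k, F_size, C_size, V_size) -> np.ndarray:
    """Vectorized upper-tail P(X >= k) of the hypergeometric distribution
    (overlap of a C_size-protein cluster with an F_size-protein functional
    group in a V_size-protein universe). Broadcasts over all arguments."""
    k, F, C, V = np.broadcast_arrays(*(np.asarray(a) for a in
                                       (k, F_size, C_size, V_size)))
    if np.any(k < 0) or np.any(k > np.minimum(F, C)):
        raise ValueError("impossible overlap count k")
    if np.any(F > V) or np.any(C > V) or np.any(F < 0) or np.any(C < 0):
        raise ValueError("group and cluster cannot exceed the universe")
    p = np.clip(stats.hypergeom.sf(k - 1, V, F, C), 0.0, 1.0)
    return np.where(k == 0, 1.0, p)


def hypergeom_pvalue(k: int, F_size: int, C_size: int, V_size: int) -> float:
    """Upper-tail P(X >= k), i.e.
    1 - sum_{i<k} C(F,i) C(V-F, C-i) / C(V,C); k = 0 gives 1."""
    return float(hypergeom_pvalues(k, F_size, C_size, V_size))


def functional_homogeneity(cluster: frozenset[str] | set[str],
                           groups: Mapping[str, Iterable[str]],
                           V_size: int, bonferroni: bool = False) -> float:
    """Smallest hypergeometric upper-tail p-value of the cluster over all
    functional groups; optionally Bonferroni-corrected."""
    if not groups:
        raise ValueError("at least one functional group is required")
    cluster = set(cluster)
    best = 1.0
    for members in groups.values():
        g = set(members)
        k = len(cluster & g)
        p = hypergeom_pvalue(k, len(g), len(cluster), V_size)
        best = min(best, p)
    if bonferroni:
        best = min(1.0, best * len(groups))
    return best


def edge_relevance_proportion(edges: Iterable[Pair],
                              similarities: Mapping[Pair, float],
                              threshold: float = 0.5) -> float:
    """Fraction of edges whose pair similarity is strictly above the
    threshold; edges missing a similarity count as below (and are logged)."""
    edges = list(edges)
    if not edges:
        return 0.0
    n_above = 0
    n_missing = 0
    for e in edges:
        pair = canonical_pair(*e)
        sim = similarities.get(pair)
        if sim is None:
            n_missing += 1
            continue
        if sim > threshold:
            n_above += 1
    if n_missing:
        logger.warning("%d/%d edges lack a similarity value; counted as "
                       "below threshold", n_missing, len(edges))
    return n_above / len(edges)
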