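"""The 17-component evidence vector describing one protein pair.

Each unordered pair of proteins is summarized by a fixed-order vector
combining six evidence sources: domain-domain interaction propensity (D),
Gene Ontology semantic similarity and GO-slim sharing in the three aspects
(MF/mf, BP/bp, CC/cc), expression correlation (CE), a STRING-like
association score (S), five AP-MS reliability scores (TAP1-TAP5), membership
in two curated PPI databases (EPPI1, EPPI2), and a shared-neighborhood
topology feature derived from the Czekanowski-Dice distance (CD).

Semantic similarity uses information content IC(t) = -log(fraction of the
annotated corpus covered by t or its descendants) and, for a term pair, the
IC-normalized most-informative-common-ancestor score
2*IC(MICA) / (IC(t_a) + IC(t_b)), averaged over all cross term pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import ASPECTS
from .io_formats import Pair, canonical_pair

logger = logging.getLogger(__name__)

#: Fixed component order of the pair vector.
PAIR_COMPONENTS = (
    "D", "MF", "mf", "BP", "bp", "CC", "cc", "CE", "S",
    "TAP1", "TAP2", "TAP3", "TAP4", "TAP5", "EPPI1", "EPPI2", "CD",
)

_ASPECT_NAMESPACE = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}


class PairVector(NamedTuple):
    """Evidence vector of one protein pair, in fixed component order."""

    D: float
    MF: float
    mf: float
    BP: float
    bp: float
    CC: float
    cc: float
    CE: float
    S: float
    TAP1: float
    TAP2: float
    TAP3: float
    TAP4: float
    TAP5: float
    EPPI1: float
    EPPI2: float
    CD: float


N_COMPONENTS = len(PAIR_COMPONENTS)
assert PairVector._fields == PAIR_COMPONENTS


@dataclass
class EvidenceBundle:
    """All evidence sources needed to build pair vectors.

    Any source may be absent (empty mapping / None); the corresponding
    features default to 0 so vectors are always complete.
    """

    go: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    slims: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    dag: nx.DiGraph | None = None
    aspect_roots: dict[str, frozenset[str]] | None = None
    expression: pd.DataFrame | None = None
    domains: dict[str, frozenset[str]] = field(default_factory=dict)
    ddi: dict[tuple[str, str], float] = field(default_factory=dict)
    string_scores: dict[Pair, float] = field(default_factory=dict)
    tap: tuple[dict[Pair, float], ...] = ({}, {}, {}, {}, {})
    eppi: tuple[frozenset[Pair], frozenset[Pair]] = (frozenset(), frozenset())
    topology: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tap) != 5:
            raise ValueError("exactly five TAP score tables required")
        if len(self.eppi) != 2:
            raise ValueError("exactly two EPPI membership sets required")
        for table in (*self.tap, self.string_scores, self.ddi):
            if any(v < 0 for v in table.values()):
                raise ValueError("score tables must be non-negative")
        if self.dag is not None and not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("ontology graph must be acyclic")
        self._ic: dict[str, dict[str, float]] = {}
        self._anc: dict[str, frozenset[str]] = {}
        self._tsim: dict[tuple[str, str, str], float] = {}
        self._corr: np.ndarray | None = None
        self._corr_index: dict[str, int] | None = None
        self._warned_expression = False

    # -- ontology machinery -------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """The term itself plus all its ancestors in the DAG."""
        cached = self._anc.get(term)
        if cached is not None:
            return cached
        if self.dag is None or term not in self.dag:
            raise KeyError(f"GO term {term!r} is not in the ontology DAG")
        anc = frozenset({term} | nx.descendants(self.dag, term))
        self._anc[term] = anc
        return anc

    def information_content(self, aspect: str) -> dict[str, float]:
        """Per-term IC for one aspect, from the aspect's annotation corpus."""
        cached = self._ic.get(aspect)
        if cached is not None:
            return cached
        annotations = self.go.get(aspect, {})
        corpus = [p for p, ts in annotations.items() if ts]
        counts: dict[str, int] = {}
        for p in corpus:
            covered: set[str] = set()
            for t in annotations[p]:
                covered |= self.ancestors(t)
            for t in covered:
                counts[t] = counts.get(t, 0) + 1
        n = len(corpus)
        ic = {t: -math.log(c / n) for t, c in counts.items()} if n else {}
        self._ic[aspect] = ic
        return ic

    def term_similarity(self, t1: str, t2: str, aspect: str) -> float:
        key = (aspect, *sorted((t1, t2)))
        cached = self._tsim.get(key)
        if cached is not None:
            return cached
        ic = self.information_content(aspect)
        common = self.ancestors(t1) & self.ancestors(t2)
        mica = max((ic.get(t, 0.0) for t in common), default=0.0)
        denom = ic.get(t1, 0.0) + ic.get(t2, 0.0)
        sim = 0.0 if denom <= 0.0 or mica <= 0.0 else 2.0 * mica / denom
        self._tsim[key] = sim
        return sim

    def roots_for(self, aspect: str) -> frozenset[str]:
        """Trivial root terms to ignore in slim comparisons."""
        if self.aspect_roots is not None:
            return self.aspect_roots.get(aspect, frozenset())
        if self.dag is None:
            return frozenset()
        namespace = _ASPECT_NAMESPACE.get(aspect)
        roots = set()
        for node in self.dag.nodes:
            if self.dag.out_degree(node) == 0:
                ns = self.dag.nodes[node].get("namespace")
                if ns is None or namespace is None or ns == namespace:
                    roots.add(node)
        return frozenset(roots)

    # -- expression machinery -----------------------------------------------

    def _correlation(self) -> tuple[np.ndarray | None, dict[str, int]]:
        if self._corr_index is not None:
            return self._corr, self._corr_index
        if self.expression is None or self.expression.shape[1] < 2:
            self._corr, self._corr_index = None, {}
            return None, {}
        values = self.expression.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values)
        if corr.ndim == 0:  # single protein
            corr = corr.reshape(1, 1)
        self._corr = corr
        self._corr_index = {p: i for i, p in enumerate(self.expression.index)}
        return self._corr, self._corr_index


# -- feature operations ------------------------------------------------------


def enumerate_pairs(proteins: Sequence[str]) -> Iterator[Pair]:
    """All n(n-1)/2 unordered pairs in lexicographic order."""
    ids = list(proteins)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein identifiers")
    yield from itertools.combinations(sorted(ids), 2)


def go_semantic_similarity(a: str, b: str, aspect: str, bundle: EvidenceBundle) -> float:
    """Average IC-normalized MICA similarity over all cross term pairs;
    0 when either protein lacks annotation in the aspect."""
    annotations = bundle.go.get(aspect, {})
    ta, tb = annotations.get(a, frozenset()), annotations.get(b, frozenset())
    if not ta or not tb:
        return 0.0
    total = 0.0
    for t1 in ta:
        for t2 in tb:
            total += bundle.term_similarity(t1, t2, aspect)
    return total / (len(ta) * len(tb))


def go_slim_similarity(a: str, b: str, aspect: str, bundle: EvidenceBundle) -> float:
    """1 iff the two proteins share a non-root GO-slim term in the aspect."""
    slims = bundle.slims.get(aspect, {})
    shared = (slims.get(a, frozenset()) & slims.get(b, frozenset())) - bundle.roots_for(aspect)
    return 1.0 if shared else 0.0


def coexpression(a: str, b: str, bundle: EvidenceBundle) -> float:
    """Pearson correlation of the two expression profiles; degenerate cases
    (missing protein, <2 samples, zero variance) return 0."""
    corr, index = bundle._correlation()
    if corr is None:
        if bundle.expression is not None and not bundle._warned_expression:
            logger.warning("expression matrix has <2 samples; CE features are 0")
            bundle._warned_expression = True
        return 0.0
    ia, ib = index.get(a), index.get(b)
    if ia is None or ib is None:
        return 0.0
    r = corr[ia, ib]
    return float(r) if math.isfinite(r) else 0.0


def ddi_score(a: str, b: str, bundle: EvidenceBundle) -> float:
    """Sum of confidences over all cross domain pairs (unordered lookup)."""
    da = bundle.domains.get(a, frozenset())
    db = bundle.domains.get(b, frozenset())
    total = 0.0
    for d1 in da:
        for d2 in db:
            key = (d1, d2) if d1 <= d2 else (d2, d1)
            total += bundle.ddi.get(key, 0.0)
    return total


def cd_distance(a: str, b: str, topology: dict[str, frozenset[str]]) -> float:
    """Czekanowski-Dice distance between interaction neighborhoods.

    N(x) is x's neighbor set plus x itself (isolated proteins use {x});
    distance = |N(a) sym-diff N(b)| / (|N(a) union N(b)| + |N(a) inter N(b)|).
    """
    na = set(topology.get(a, frozenset())) | {a}
    nb = set(topology.get(b, frozenset())) | {b}
    sym = len(na ^ nb)
    return sym / (len(na | nb) + len(na & nb))


def build_pair_vector(pair: Pair, bundle: EvidenceBundle, cd_raw: bool = False) -> PairVector:
    """Assemble the full 17-component vector for one canonical pair.

    Missing sources contribute 0; the stored CD feature is 1 - distance
    (larger = stronger evidence) unless ``cd_raw`` is set.
    """
    a, b = canonical_pair(*pair)
    dist = cd_distance(a, b, bundle.topology)
    return PairVector(
        D=ddi_score(a, b, bundle),
        MF=go_semantic_similarity(a, b, "MF", bundle),
        mf=go_slim_similarity(a, b, "MF", bundle),
        BP=go_semantic_similarity(a, b, "BP", bundle),
        bp=go_slim_similarity(a, b, "BP", bundle),
        CC=go_semantic_similarity(a, b, "CC", bundle),
        cc=go_slim_similarity(a, b, "CC", bundle),
        CE=coexpression(a, b, bundle),
        S=bundle.string_scores.get((a, b), 0.0),
        TAP1=bundle.tap[0].get((a, b), 0.0),
        TAP2=bundle.tap[1].get((a, b), 0.0),
        TAP3=bundle.tap[2].get((a, b), 0.0),
        TAP4=bundle.tap[3].get((a, b), 0.0),
        TAP5=bundle.tap[4].get((a, b), 0.0),
        EPPI1=1.0 if (a, b) in bundle.eppi[0] else 0.0,
        EPPI2=1.0 if (a, b) in bundle.eppi[1] else 0.0,
        CD=dist if cd_raw else 1.0 - dist,
    )


def build_pair_vectors(pairs: Iterable[Pair], bundle: EvidenceBundle,
                       cd_raw: bool = False) -> Iterator[tuple[Pair, PairVector]]:
    """Stream (pair, vector) for many pairs, sharing the bundle's caches."""
    for pair in pairs:
        yield pair, build_pair_vector(pair, bundle, cd_raw=cd_raw)
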