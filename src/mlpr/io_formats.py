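"""Readers and writers for the plain-text tables the pipeline consumes.

Every format is UTF-8, tab-separated; lines whose first non-blank character
is ``#`` are comments. Protein pairs are stored canonically with the
lexicographically smaller identifier first, self-pairs are dropped, and
duplicate weighted edges are collapsed keeping the maximum score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


class ParseError(ValueError):
    """Raised when an input table violates its format contract."""


def canonical_pair(a: str, b: str) -> Pair:
    """Order a pair lexicographically; self-pairs are the caller's problem."""
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True, slots=True)
class EdgeRecord:
    """One undirected, canonically ordered protein pair with an optional score."""

    a: str
    b: str
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.a >= self.b:
            raise ValueError(f"edge not canonical: {self.a!r} >= {self.b!r}")
        if self.weight is not None and self.weight < 0:
            raise ValueError(f"negative weight {self.weight} on ({self.a}, {self.b})")

    @property
    def pair(self) -> Pair:
        return (self.a, self.b)


@dataclass(frozen=True)
class ComplexSet:
    """An ordered collection of protein complexes (each a protein set)."""

    complexes: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def filter_min_size(self, min_size: int) -> "ComplexSet":
        return ComplexSet(tuple(c for c in self.complexes if len(c) >= min_size))

    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return frozenset(out)


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, has_weight: bool | None = None) -> set[EdgeRecord]:
    """Read a 2- or 3-column edge list into a canonical, deduplicated edge set.

    ``has_weight=None`` infers the dialect from the first data row. Duplicate
    pairs keep the maximum weight; self-pairs are dropped.
    """
    best: dict[Pair, float | None] = {}
    for lineno, line in _data_lines(path):
        if not line.strip():
            continue
        cols = line.split("\t")
        if has_weight is None:
            has_weight = len(cols) == 3
        want = 3 if has_weight else 2
        if len(cols) != want:
            raise ParseError(f"{path}:{lineno}: expected {want} columns, got {len(cols)}")
        a, b = cols[0].strip(), cols[1].strip()
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty protein identifier")
        w: float | None = None
        if has_weight:
            try:
                w = float(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {cols[2]!r}") from exc
            if not math.isfinite(w) or w < 0:
                raise ParseError(f"{path}:{lineno}: weight must be finite and >= 0, got {cols[2]}")
        if a == b:
            logger.debug("%s:%d: dropping self-pair %s", path, lineno, a)
            continue
        pair = canonical_pair(a, b)
        if pair in best:
            prev = best[pair]
            if w is not None and (prev is None or w > prev):
                best[pair] = w
        else:
            best[pair] = w
    return {EdgeRecord(a, b, w) for (a, b), w in best.items()}


def edge_pairs(edges: Iterable[EdgeRecord]) -> frozenset[Pair]:
    return frozenset(e.pair for e in edges)


def edge_score_map(edges: Iterable[EdgeRecord], default: float = 1.0) -> dict[Pair, float]:
    return {e.pair: (default if e.weight is None else e.weight) for e in edges}


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column (protein, term) multimap; absent proteins simply
    have no entry, so look up with ``.get(p, frozenset())``."""
    out: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        protein, term = cols[0].strip(), cols[1].strip()
        if not protein or not term:
            raise ParseError(f"{path}:{lineno}: empty protein or term")
        out.setdefault(protein, set()).add(term)
    return {p: frozenset(ts) for p, ts in out.items()}


def read_expression_matrix(path: str | Path, log_transform: bool = False) -> pd.DataFrame:
    """Read a protein x sample expression table (header row of sample IDs,
    first column protein ID). With ``log_transform``, values become
    log2(x + 1)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate protein row {dup!r}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric values in column(s) {non_numeric}")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing or ragged cells")
    if log_transform:
        if (df.values <= -1).any():
            raise ParseError(f"{path}: log2(x+1) undefined for values <= -1")
        import numpy as np

        df = pd.DataFrame(np.log2(df.values + 1.0), index=df.index, columns=df.columns)
    df.index = df.index.astype(str)
    return df


def read_complexes(path: str | Path, min_size: int = 1) -> ComplexSet:
    """Read one complex per line (tab-separated members). Members are
    deduplicated per line; blank lines are skipped with a warning; complexes
    smaller than ``min_size`` are dropped."""
    complexes: list[frozenset[str]] = []
    for lineno, line in _data_lines(path):
        if not line.strip():
            logger.warning("%s:%d: skipping blank complex line", path, lineno)
            continue
        members = frozenset(m.strip() for m in line.split("\t") if m.strip())
        if not members:
            logger.warning("%s:%d: skipping blank complex line", path, lineno)
            continue
        if len(members) >= min_size:
            complexes.append(members)
    return ComplexSet(tuple(complexes))


def write_complexes(complexes: ComplexSet, path: str | Path,
                    scores: Iterable[float] | None = None) -> None:
    """Write one complex per line; with ``scores``, prepend a score column."""
    score_list = list(scores) if scores is not None else None
    with open(path, "w", encoding="utf-8") as fh:
        for i, c in enumerate(complexes):
            members = "\t".join(sorted(c))
            if score_list is not None:
                fh.write(f"{score_list[i]!r}\t{members}\n")
            else:
                fh.write(members + "\n")


def write_weighted_edges(network, path: str | Path) -> None:
    """Write a 3-column weighted edge list in descending score order
    (ties broken by lexicographic pair); readable back by read_edge_list."""
    if hasattr(network, "edges"):
        rows = list(network.edges)
    else:
        rows = list(network)
    for a, b, w in rows:
        if not math.isfinite(w):
            raise ValueError(f"non-finite score on ({a}, {b})")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_ontology(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology into a child->parent DiGraph.

    Only ``is_a`` and ``part_of`` relations are kept as hierarchy edges;
    node attributes (name, namespace) are preserved. Raises if the result
    is not acyclic.
    """
    multi = obonet.read_obo(path)
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, **data)
    for u, v, key in multi.edges(keys=True):
        if key in ("is_a", "part_of"):
            dag.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(dag):
        raise ParseError(f"{path}: ontology graph contains a cycle")
    return dag


def read_pair_scores(path: str | Path) -> dict[Pair, float]:
    """Read a 3-column pair-score table into a canonical pair -> score map."""
    return edge_score_map(read_edge_list(path, has_weight=True))
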