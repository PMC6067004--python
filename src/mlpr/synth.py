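"""Seedable synthetic fixtures: planted complexes, a true PPI network, and
all six evidence sources in the pipeline's file dialects.

The generator plants disjoint complexes in a protein universe, draws a true
interaction network (dense inside complexes, sparse background), and then
emulates each evidence source around that truth:

* expression — one latent factor per complex, giving co-complex profiles a
  pairwise Pearson correlation of about ``rho``;
* ontology — a three-aspect DAG (root -> branch -> leaf) where each complex
  owns a leaf term its members carry with probability ``annotation_prob``,
  plus background leaves; slim terms are the branch level;
* domains — each complex owns a high-confidence interacting domain pair
  split among its members, plus background domains with weak DDI scores;
* observed PPI databases (two EPPI sets), five AP-MS score tables, and a
  STRING-like score table — independently false-positive/false-negative
  corrupted copies of the true edge set, retained true edges scoring
  Beta(5, 2) and spurious ones Beta(2, 5).

Everything derives deterministically from (TruthSpec, rng_seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .config import ASPECTS, RunConfig
from .io_formats import ComplexSet, Pair, canonical_pair
from .pair_features import EvidenceBundle

logger = logging.getLogger(__name__)

_NAMESPACE = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}


@dataclass(frozen=True)
class TruthSpec:
    """Study conditions of the synthetic regime."""

    n_proteins: int = 300
    n_complexes: int = 20
    min_size: int = 5
    max_size: int = 8
    p_in: float = 0.9       # within-complex edge probability
    p_bg: float = 0.005     # background edge probability
    fp: float = 0.1         # false-positive rate per observed source
    fn: float = 0.1         # false-negative rate per observed source
    m_samples: int = 50     # expression samples
    rho: float = 0.7        # within-complex expression correlation
    annotation_prob: float = 0.8  # complex-term sharing probability
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_bg", "fp", "fn", "rho", "annotation_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_in <= self.p_bg:
            raise ValueError("p_in must exceed p_bg")
        if self.min_size < 3:
            raise ValueError("complex sizes must be >= 3")
        if self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")
        if self.n_complexes * self.max_size > self.n_proteins:
            raise ValueError("complex members cannot exceed the protein count")


@dataclass(frozen=True)
class SyntheticFixture:
    spec: TruthSpec
    proteins: tuple[str, ...]
    complexes: ComplexSet
    true_edges: frozenset[Pair]
    bundle: EvidenceBundle
    obo_text: str


def _rng(spec: TruthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed, stream])


def generate_truth(spec: TruthSpec) -> tuple[tuple[str, ...], ComplexSet, frozenset[Pair]]:
    """Plant disjoint complexes and draw the true interaction network."""
    rng = _rng(spec, 0)
    n = spec.n_proteins
    proteins = tuple(f"P{i:04d}" for i in range(n))
    sizes = rng.integers(spec.min_size, spec.max_size + 1, size=spec.n_complexes)
    if sizes.sum() > n:
        raise ValueError("infeasible spec: more complex members than proteins")
    order = rng.permutation(n)
    complexes = []
    pos = 0
    membership = np.full(n, -1, dtype=np.int64)
    for c, size in enumerate(sizes):
        idx = order[pos:pos + size]
        pos += size
        membership[idx] = c
        complexes.append(frozenset(proteins[i] for i in idx))
    ii, jj = np.triu_indices(n, k=1)
    same = (membership[ii] >= 0) & (membership[ii] == membership[jj])
    prob = np.where(same, spec.p_in, spec.p_bg)
    drawn = rng.random(ii.size) < prob
    true_edges = frozenset(
        canonical_pair(proteins[i], proteins[j])
        for i, j in zip(ii[drawn], jj[drawn])
    )
    return proteins, ComplexSet(tuple(complexes)), true_edges


def _corrupt_edges(true_edges: frozenset[Pair], proteins: tuple[str, ...],
                   fp: float, fn: float,
                   rng: np.random.Generator) -> tuple[frozenset[Pair], frozenset[Pair]]:
    """(retained true edges, spurious edges) under the fp/fn noise model.

    Each true edge is dropped with probability fn; round(fp * |E|) distinct
    non-edges are added.
    """
    edges = sorted(true_edges)
    keep_mask = rng.random(len(edges)) >= fn
    kept = frozenset(e for e, keep in zip(edges, keep_mask) if keep)
    n_fp = int(round(fp * len(edges)))
    spurious: set[Pair] = set()
    n = len(proteins)
    while len(spurious) < n_fp:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = canonical_pair(proteins[i], proteins[j])
        if pair in true_edges or pair in spurious:
            continue
        spurious.add(pair)
    return kept, frozenset(spurious)


def _score_table(kept: frozenset[Pair], spurious: frozenset[Pair],
                 rng: np.random.Generator) -> dict[Pair, float]:
    kept_l, spur_l = sorted(kept), sorted(spurious)
    scores = {}
    for pair, s in zip(kept_l, rng.beta(5.0, 2.0, size=len(kept_l))):
        scores[pair] = float(s)
    for pair, s in zip(spur_l, rng.beta(2.0, 5.0, size=len(spur_l))):
        scores[pair] = float(s)
    return scores


def _build_ontology(spec: TruthSpec) -> tuple[nx.DiGraph, str, dict[str, dict[str, str]]]:
    """Three-aspect DAG: root -> 8 branches -> background + complex leaves.

    Returns (dag, obo text, term ids per aspect: role -> term)."""
    n_branches, n_bg = 8, 16
    dag = nx.DiGraph()
    blocks: list[str] = ["format-version: 1.2\nontology: synthetic-fixture\n"]
    terms: dict[str, dict[str, str]] = {}

    def add(term: str, name: str, aspect: str, parent: str | None) -> None:
        dag.add_node(term, name=name, namespace=_NAMESPACE[aspect])
        block = [f"[Term]", f"id: {term}", f"name: {name}",
                 f"namespace: {_NAMESPACE[aspect]}"]
        if parent is not None:
            dag.add_edge(term, parent)
            block.append(f"is_a: {parent}")
        blocks.append("\n".join(block) + "\n")

    for ai, aspect in enumerate(ASPECTS, start=1):
        t = terms[aspect] = {}
        root = f"GO:{ai}000000"
        t["root"] = root
        add(root, f"{aspect.lower()}_root", aspect, None)
        for b in range(n_branches):
            term = f"GO:{ai}00{b + 1:02d}00"
            t[f"branch{b}"] = term
            add(term, f"{aspect.lower()}_branch_{b}", aspect, root)
        for g in range(n_bg):
            term = f"GO:{ai}01{g:02d}01"
            t[f"bg{g}"] = term
            add(term, f"{aspect.lower()}_background_{g}", aspect,
                t[f"branch{g % n_branches}"])
        for c in range(spec.n_complexes):
            term = f"GO:{ai}02{c:02d}01"
            t[f"complex{c}"] = term
            add(term, f"{aspect.lower()}_complex_{c}", aspect,
                t[f"branch{c % n_branches}"])
    return dag, "\n".join(blocks), terms


def generate_fixture(spec: TruthSpec) -> SyntheticFixture:
    """Generate truth plus a complete evidence bundle."""
    proteins, complexes, true_edges = generate_truth(spec)
    n = spec.n_proteins
    member_of = {p: c for c, members in enumerate(complexes) for p in members}

    # expression: shared latent factor per complex
    rng = _rng(spec, 1)
    latent = rng.normal(size=(spec.n_complexes, spec.m_samples))
    noise = rng.normal(size=(n, spec.m_samples))
    X = np.sqrt(1.0 - spec.rho) * noise
    for i, p in enumerate(proteins):
        c = member_of.get(p)
        if c is not None:
            X[i] += np.sqrt(spec.rho) * latent[c]
        else:
            X[i] = noise[i]
    expression = pd.DataFrame(
        X, index=list(proteins),
        columns=[f"S{j:03d}" for j in range(spec.m_samples)])

    # ontology, annotations, slims
    dag, obo_text, terms = _build_ontology(spec)
    n_bg = 16
    go: dict[str, dict[str, frozenset[str]]] = {}
    slims: dict[str, dict[str, frozenset[str]]] = {}
    leaf_branch = {
        aspect: {t[f"complex{c}"]: t[f"branch{c % 8}"]
                 for c in range(spec.n_complexes)}
        | {t[f"bg{g}"]: t[f"branch{g % 8}"] for g in range(n_bg)}
        for aspect, t in terms.items()
    }
    for ai, aspect in enumerate(ASPECTS):
        rng_a = _rng(spec, 10 + ai)
        annot: dict[str, set[str]] = {}
        for i, p in enumerate(proteins):
            ts = {terms[aspect][f"bg{int(rng_a.integers(0, n_bg))}"]}
            c = member_of.get(p)
            if c is not None and rng_a.random() < spec.annotation_prob:
                ts.add(terms[aspect][f"complex{c}"])
            annot[p] = ts
        go[aspect] = {p: frozenset(ts) for p, ts in annot.items()}
        slims[aspect] = {
            p: frozenset(leaf_branch[aspect][t] for t in ts)
            for p, ts in annot.items()
        }

    # domains and DDI confidences
    rng_d = _rng(spec, 20)
    bg_domains = [f"DM9{g:03d}" for g in range(10)]
    domains: dict[str, set[str]] = {p: set() for p in proteins}
    ddi: dict[tuple[str, str], float] = {}
    for c in range(spec.n_complexes):
        da, db = f"DM{c:03d}A", f"DM{c:03d}B"
        key = (da, db) if da <= db else (db, da)
        ddi[key] = float(rng_d.uniform(0.5, 1.0))
        for p in sorted(complexes[c]):
            domains[p].add(da if rng_d.random() < 0.5 else db)
    for p in proteins:
        domains[p].add(bg_domains[int(rng_d.integers(0, len(bg_domains)))])
    for _ in range(10):
        d1, d2 = (bg_domains[int(rng_d.integers(0, 10))] for _ in range(2))
        if d1 == d2:
            continue
        key = (d1, d2) if d1 <= d2 else (d2, d1)
        ddi.setdefault(key, float(rng_d.uniform(0.0, 0.2)))

    # observed networks and score tables
    eppi_sets = []
    for k in range(2):
        kept, spur = _corrupt_edges(true_edges, proteins, spec.fp, spec.fn,
                                    _rng(spec, 30 + k))
        eppi_sets.append(kept | spur)
    tap_tables = []
    for k in range(5):
        rng_t = _rng(spec, 40 + k)
        kept, spur = _corrupt_edges(true_edges, proteins, spec.fp, spec.fn, rng_t)
        tap_tables.append(_score_table(kept, spur, rng_t))
    rng_s = _rng(spec, 50)
    kept, spur = _corrupt_edges(true_edges, proteins, spec.fp, spec.fn, rng_s)
    string_scores = _score_table(kept, spur, rng_s)

    adj: dict[str, set[str]] = {}
    for a, b in eppi_sets[0]:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    topology = {p: frozenset(s) for p, s in adj.items()}

    bundle = EvidenceBundle(
        go=go, slims=slims, dag=dag, expression=expression,
        domains={p: frozenset(s) for p, s in domains.items()},
        ddi=ddi, string_scores=string_scores, tap=tuple(tap_tables),
        eppi=(frozenset(eppi_sets[0]), frozenset(eppi_sets[1])),
        topology=topology,
    )
    return SyntheticFixture(spec=spec, proteins=proteins, complexes=complexes,
                            true_edges=true_edges, bundle=bundle,
                            obo_text=obo_text)


# -- serialization -----------------------------------------------------------

PRESETS = {
    "easy": TruthSpec(),
    "hard": TruthSpec(p_in=0.7, p_bg=0.01, fp=0.25, fn=0.3, rho=0.4,
                      annotation_prob=0.5),
}


def _write_two_col(path: Path, mapping: dict[str, frozenset[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(mapping):
            for value in sorted(mapping[key]):
                fh.write(f"{key}\t{value}\n")


def _write_pairs(path: Path, pairs) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def _write_scores(path: Path, scores: dict, weight_repr=repr) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(scores):
            a, b = key
            fh.write(f"{a}\t{b}\t{weight_repr(scores[key])}\n")


def write_fixture(fixture: SyntheticFixture, out_dir: str | Path) -> Path:
    """Write every source file plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = fixture.spec
    bundle = fixture.bundle

    (out / "ontology.obo").write_text(fixture.obo_text, encoding="utf-8")
    for aspect in ASPECTS:
        _write_two_col(out / f"go_{aspect.lower()}.tsv", bundle.go[aspect])
        _write_two_col(out / f"slim_{aspect.lower()}.tsv", bundle.slims[aspect])
    bundle.expression.to_csv(out / "expression.tsv", sep="\t",
                             index_label="protein")
    _write_two_col(out / "domains.tsv", bundle.domains)
    _write_scores(out / "ddi.tsv", bundle.ddi)
    _write_scores(out / "string.tsv", bundle.string_scores)
    for k in range(5):
        _write_scores(out / f"tap{k + 1}.tsv", bundle.tap[k])
    for k in range(2):
        _write_pairs(out / f"eppi{k + 1}.tsv", bundle.eppi[k])
    with open(out / "complexes_truth.tsv", "w", encoding="utf-8") as fh:
        for c in fixture.complexes:
            fh.write("\t".join(sorted(c)) + "\n")
    _write_pairs(out / "true_edges.tsv", fixture.true_edges)
    with open(out / "proteins.tsv", "w", encoding="utf-8") as fh:
        for p in fixture.proteins:
            fh.write(p + "\n")

    manifest = {
        "seed": spec.rng_seed,
        "spec": dataclasses.asdict(spec),
        # suggested operating point: keep as many top-ranked pairs as the
        # regime plants true edges
        "config": {"log_expression": False, "top_n": len(fixture.true_edges)},
        "sources": {
            "proteins": "proteins.tsv",
            "ontology": "ontology.obo",
            "go": {a: f"go_{a.lower()}.tsv" for a in ASPECTS},
            "slim": {a: f"slim_{a.lower()}.tsv" for a in ASPECTS},
            "expression": "expression.tsv",
            "domains": "domains.tsv",
            "ddi": "ddi.tsv",
            "string": "string.tsv",
            "tap": [f"tap{k + 1}.tsv" for k in range(5)],
            "eppi": ["eppi1.tsv", "eppi2.tsv"],
            "topology": "eppi1.tsv",
        },
        "truth": {
            "complexes": "complexes_truth.tsv",
            "edges": "true_edges.tsv",
        },
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
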