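"""End-to-end orchestration: manifest loading, reconstruction, detection.

The manifest is a YAML file with a ``sources`` section naming each evidence
table (absent entries permitted), an optional ``config`` section of run
parameters, and an optional ``truth`` section for synthetic fixtures.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .config import ASPECTS, RunConfig
from .fingerprinting import FingerprintTable, SimilarityGraph, assign_fingerprints, build_knn_graph
from .io_formats import (ComplexSet, Pair, edge_pairs, read_annotations,
                         read_complexes, read_edge_list,
                         read_expression_matrix, read_ontology,
                         read_pair_scores)
from .pair_features import EvidenceBundle, build_pair_vectors, enumerate_pairs
from .reconstruct import (ReconstructedNetwork, RWRResult,
                          random_walk_with_restart, score_and_rank_pairs,
                          seed_priors, select_top)

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    yield
    logger.info("stage %-24s %8.2f s", name, time.perf_counter() - t0)


def load_bundle(manifest_path: str | Path,
                config: RunConfig | None = None) -> tuple[EvidenceBundle, tuple[str, ...]]:
    """Assemble an evidence bundle from a manifest; returns (bundle, proteins).

    The protein universe is the explicit ``proteins`` file when present,
    otherwise the union of identifiers seen across all sources.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    sources = doc.get("sources", {})
    base = manifest_path.parent

    def path_of(entry: str) -> Path:
        return base / entry

    cfg = config or RunConfig.from_mapping(doc.get("config", {}))

    go = {}
    slims = {}
    for aspect in ASPECTS:
        entry = sources.get("go", {}).get(aspect)
        if entry:
            go[aspect] = read_annotations(path_of(entry))
        entry = sources.get("slim", {}).get(aspect)
        if entry:
            slims[aspect] = read_annotations(path_of(entry))
    dag = read_ontology(path_of(sources["ontology"])) if sources.get("ontology") else None
    expression = None
    if sources.get("expression"):
        expression = read_expression_matrix(path_of(sources["expression"]),
                                            log_transform=cfg.log_expression)
    domains = read_annotations(path_of(sources["domains"])) if sources.get("domains") else {}
    ddi = {}
    if sources.get("ddi"):
        ddi = {tuple(sorted(k)): v
               for k, v in read_pair_scores(path_of(sources["ddi"])).items()}
    string_scores = read_pair_scores(path_of(sources["string"])) if sources.get("string") else {}
    tap = tuple(
        read_pair_scores(path_of(entry)) if entry else {}
        for entry in (sources.get("tap") or [None] * 5)
    )
    if len(tap) != 5:
        raise ValueError("manifest must name five TAP tables (entries may be null)")
    eppi = tuple(
        edge_pairs(read_edge_list(path_of(entry), has_weight=False)) if entry else frozenset()
        for entry in (sources.get("eppi") or [None, None])
    )
    topology: dict[str, frozenset[str]] = {}
    if sources.get("topology"):
        adj: dict[str, set[str]] = {}
        for e in read_edge_list(path_of(sources["topology"])):
            adj.setdefault(e.a, set()).add(e.b)
            adj.setdefault(e.b, set()).add(e.a)
        topology = {p: frozenset(s) for p, s in adj.items()}

    bundle = EvidenceBundle(go=go, slims=slims, dag=dag, expression=expression,
                            domains=domains, ddi=ddi,
                            string_scores=string_scores, tap=tap, eppi=eppi,
                            topology=topology)

    if sources.get("proteins"):
        with open(path_of(sources["proteins"]), encoding="utf-8") as fh:
            proteins = tuple(line.strip() for line in fh if line.strip()
                             and not line.startswith("#"))
    else:
        universe: set[str] = set()
        for mapping in (*go.values(), *slims.values(), domains, topology):
            universe |= set(mapping)
        if expression is not None:
            universe |= set(expression.index)
        for table in (string_scores, *tap):
            for a, b in table:
                universe |= {a, b}
        for s in eppi:
            for a, b in s:
                universe |= {a, b}
        proteins = tuple(sorted(universe))
    return bundle, proteins


@dataclass(frozen=True)
class ReconstructionResult:
    table: FingerprintTable
    graph: SimilarityGraph
    seeds: np.ndarray
    rwr: RWRResult
    ranked: list[tuple[Pair, float]]
    network: ReconstructedNetwork


def reconstruct_network(bundle: EvidenceBundle, proteins: tuple[str, ...],
                        cfg: RunConfig) -> ReconstructionResult:
    """Run the full reconstruction: vectors -> fingerprints -> kNN graph ->
    restart walk -> ranked top-N weighted network."""
    with _stage("pair vectors"):
        items = list(build_pair_vectors(enumerate_pairs(proteins), bundle,
                                        cd_raw=cfg.cd_raw_distance))
    with _stage("fingerprints"):
        table = assign_fingerprints(items, precision=cfg.quantize_precision)
    logger.info("%d pairs -> %d fingerprints", table.n_pairs,
                table.n_fingerprints)
    with _stage("similarity graph"):
        graph = build_knn_graph(table, T=cfg.T)
    with _stage("random walk"):
        f0, seeds = seed_priors(table, cfg.seed_indicators,
                                cfg.seed_min_indicators)
        rwr = random_walk_with_restart(graph.transition, f0, alpha=cfg.alpha,
                                       tol=cfg.tol, max_iter=cfg.max_iter)
    logger.info("%d seed fingerprints; converged in %d iterations",
                seeds.size, rwr.n_iter)
    with _stage("ranking"):
        ranked = score_and_rank_pairs(rwr.posterior, table)
        network = select_top(ranked, cfg.top_n)
    return ReconstructionResult(table=table, graph=graph, seeds=seeds,
                                rwr=rwr, ranked=ranked, network=network)


def run_detection(network: ReconstructedNetwork, cfg: RunConfig) -> ComplexSet:
    from .complexes import detect_complexes

    with _stage("complex detection"):
        return detect_complexes(network.to_graph(), T_in=cfg.T_in, d=cfg.d,
                                min_complex_size=cfg.min_complex_size,
                                allow_overlap=cfg.allow_overlap,
                                skip_singleton_seed=cfg.skip_singleton_seed)


def run_synthetic_benchmark(spec=None, cfg: RunConfig | None = None) -> dict:
    """Full pipeline on a synthetic fixture, scored against its planted truth.

    The reconstructed network is truncated to the number of true edges (when
    ``cfg.top_n`` is unset) so that edge precision is comparable with the
    density-matched random baseline |E_true| / C(n, 2). Returns a flat
    metrics dict.
    """
    import math

    from .evaluate import precision_recall_f
    from .synth import TruthSpec, generate_fixture

    spec = spec or TruthSpec()
    fixture = generate_fixture(spec)
    n_true = len(fixture.true_edges)
    cfg = cfg or RunConfig()
    if cfg.top_n is None:
        import dataclasses

        cfg = dataclasses.replace(cfg, top_n=n_true)
    result = reconstruct_network(fixture.bundle, fixture.proteins, cfg)

    n = len(fixture.proteins)
    n_pairs = math.comb(n, 2)
    true_hits = sum(1 for a, b, _ in result.network.edges
                    if (a, b) in fixture.true_edges)
    edge_precision = true_hits / len(result.network) if len(result.network) else 0.0
    baseline = n_true / n_pairs

    p2f = result.table.pair_to_fid()
    post = result.rwr.posterior
    true_scores = np.array([post[p2f[p]] for p in fixture.true_edges])
    other_scores = np.array([post[p2f[p]] for p in p2f
                             if p not in fixture.true_edges])

    predicted = run_detection(result.network, cfg)
    summary = precision_recall_f(predicted, fixture.complexes, omega=cfg.omega)
    return {
        "n_proteins": n,
        "n_true_edges": n_true,
        "n_fingerprints": result.table.n_fingerprints,
        "n_seed_fingerprints": int(result.seeds.size),
        "n_rwr_iterations": result.rwr.n_iter,
        "edge_precision": edge_precision,
        "baseline_precision": baseline,
        "precision_ratio": edge_precision / baseline,
        "median_posterior_true_edges": float(np.median(true_scores)),
        "median_posterior_other_pairs": float(np.median(other_scores)),
        "n_predicted_complexes": summary.n_pred,
        "complex_precision": summary.precision,
        "complex_recall": summary.recall,
        "complex_f_value": summary.f_value,
        "omega": cfg.omega,
    }
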