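"""Run configuration for the reconstruction / detection pipeline.

All tunables of the method live here: the fingerprint-graph neighbor count
``T``, the restart probability ``alpha`` of the random walk, its convergence
tolerance, the cluster-expansion threshold ``T_in`` and diameter bound ``d``,
and the neighborhood-affinity match threshold ``omega`` used in evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The three Gene Ontology aspects used for annotation-based features.
ASPECTS = ("MF", "BP", "CC")


@dataclass
class RunConfig:
    """Parameters controlling every pipeline stage.

    Defaults follow the method's stated operating point: each fingerprint is
    linked to its ``T=10`` most similar fingerprints, the walk restarts with
    probability ``alpha=0.8`` and stops when the L1 step difference falls
    below ``tol=1e-6``, clusters admit a neighbor when its interaction
    probability reaches ``T_in=0.6`` while the cluster diameter stays within
    ``d=2`` hops, and a predicted complex matches a benchmark complex when
    their neighborhood affinity reaches ``omega=0.25``.
    """

    T: int = 10
    alpha: float = 0.8
    tol: float = 1e-6
    max_iter: int = 10_000
    top_n: int | None = None
    T_in: float = 0.6
    d: int = 2
    omega: float = 0.25
    min_complex_size: int = 3
    quantize_precision: int = 4
    rng_seed: int = 0
    # log2(x+1)-transform expression values at read time
    log_expression: bool = False
    # which vector components count as "accurate PPI database" membership
    # indicators for the walk's seed rule, and how many must be non-zero
    seed_indicators: tuple[str, ...] = ("EPPI1", "EPPI2", "TAP1", "TAP5")
    seed_min_indicators: int = 2
    # store the raw Czekanowski-Dice distance instead of 1 - distance
    cd_raw_distance: bool = False
    # allow proteins removed from the seed queue to join later clusters
    allow_overlap: bool = True
    # do not bootstrap-expand a seed whose cluster has zero internal weight
    skip_singleton_seed: bool = False
    # Bonferroni-correct functional-homogeneity p-values
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 <= self.T_in <= 1.0):
            raise ValueError(f"T_in must be in [0, 1], got {self.T_in}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if not (0.0 < self.omega <= 1.0):
            raise ValueError(f"omega must be in (0, 1], got {self.omega}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.quantize_precision < 0:
            raise ValueError("quantize_precision must be >= 0")
        if self.min_complex_size < 1:
            raise ValueError("min_complex_size must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        """Build a config from a flat key/value mapping, ignoring unknown keys."""
        names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in mapping.items() if k in names}
        if "seed_indicators" in kwargs:
            kwargs["seed_indicators"] = tuple(kwargs["seed_indicators"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        # manifests nest run parameters under a 'config' section
        section = doc.get("config", doc)
        return cls.from_mapping(section)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_indicators"] = list(self.seed_indicators)
        return d
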