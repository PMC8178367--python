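"""Domain types shared by every pipeline stage.

All containers are plain dataclasses around pandas / numpy objects; validation
happens at construction so downstream stages can assume the invariants hold.
Conditions are always the two labels ``treated`` and ``control``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ParameterError

TREATED = "treated"
CONTROL = "control"
CONDITIONS = (TREATED, CONTROL)

#: Signed z assigned to genes whose two-sided p underflows to 0 (zero-variance
#: degenerate case); the inverse normal is infinite there.
Z_DEGENERATE = 38.0


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for genes x samples with condition labels.

    ``values`` is a DataFrame indexed by gene id with one column per sample.
    ``condition_of`` maps every sample id to ``treated`` or ``control``; both
    conditions must be present with at least two replicates each.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ConfigError(f"samples without condition label: {missing}")
        counts = {c: 0 for c in CONDITIONS}
        for s in self.values.columns:
            cond = self.condition_of[s]
            if cond not in CONDITIONS:
                raise ConfigError(f"unknown condition {cond!r} for sample {s!r}")
            counts[cond] += 1
        for cond, n in counts.items():
            if n < 2:
                raise ConfigError(f"condition {cond!r} has {n} replicate(s); need >= 2")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def group_values(self, condition: str) -> np.ndarray:
        """Genes x replicates array for one condition, in column order."""
        return self.values[self.samples_for(condition)].to_numpy(dtype=float)


def _canonical_edges(
    genes: frozenset[str], edges
) -> tuple[tuple[str, str, int], ...]:
    """Drop self-loops, collapse duplicate (unordered) edges, check endpoints."""
    seen: dict[frozenset, tuple[str, str, int]] = {}
    for u, v, sign in edges:
        if u == v:
            continue
        if u not in genes or v not in genes:
            raise FormatError(f"edge endpoint outside pathway genes: ({u!r}, {v!r})")
        key = frozenset((u, v))
        if key not in seen or (seen[key][2] == 0 and sign != 0):
            a, b = sorted((u, v))
            seen[key] = (a, b, int(sign))
    return tuple(sorted(seen.values()))


@dataclass(frozen=True)
class PathwayGraph:
    """A named gene set with optional signed gene-gene interaction edges.

    Edges are undirected for the purposes of connectivity and subpathway
    search; ``sign`` is +1 (activation), -1 (inhibition) or 0 (unsigned).
    """

    pathway_id: str
    name: str
    genes: frozenset[str]
    edges: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"pathway {self.pathway_id!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "edges", _canonical_edges(self.genes, self.edges))

    def with_edges(self, edges) -> "PathwayGraph":
        return PathwayGraph(self.pathway_id, self.name, self.genes, tuple(edges))

    def adjacency(self, nodes=None) -> dict[str, set[str]]:
        """Undirected adjacency restricted to ``nodes`` (default: all genes)."""
        keep = self.genes if nodes is None else set(nodes)
        adj: dict[str, set[str]] = {g: set() for g in keep}
        for u, v, _ in self.edges:
            if u in keep and v in keep:
                adj[u].add(v)
                adj[v].add(u)
        return adj


@dataclass
class RunConfig:
    """Run-wide thresholds and knobs; defaults mirror the study's filters
    (fold change >= 2, p < 0.01) and conventional pathway-testing settings."""

    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    min_measured_genes: int = 3
    permutations: int = 1000
    rng_seed: int = 0
    weight_scheme: str = "unit"  # or "abs_log2fc"
    use_absolute_z: bool = True
    alpha: float = 0.05
    search_seeds: int = 5  # k highest-|z| seeds for the subpathway search
    drop_incomplete: bool = True
    top_n: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ParameterError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if self.fc_threshold <= 1:
            raise ParameterError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if self.permutations < 1:
            raise ParameterError("permutations must be >= 1")
        if self.min_measured_genes < 1:
            raise ParameterError("min_measured_genes must be >= 1")
        if self.weight_scheme not in ("unit", "abs_log2fc"):
            raise ParameterError(f"unknown weight_scheme {self.weight_scheme!r}")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0,1)")
        if self.search_seeds < 1:
            raise ParameterError("search_seeds must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str], **overrides) -> "RunConfig":
        """Build a config from flat string key-value pairs (file or CLI)."""
        kwargs = {}
        hints = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, raw in mapping.items():
            if key not in hints:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(raw, hints[key], key)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(raw, type_name: str, key: str):
    if not isinstance(raw, str):
        return raw
    if type_name == "bool":
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise ConfigError(f"cannot parse boolean {key}={raw!r}")
    if type_name == "int":
        return int(raw)
    if type_name == "float":
        return float(raw)
    return raw


@dataclass(frozen=True)
class GeneStat:
    """Per-gene two-condition summary: fold change, p, signed z and the
    up/down/unchanged volcano call."""

    gene: str
    mean_treated: float
    mean_control: float
    log2fc: float
    fold_change: float
    p_value: float
    z_score: float
    call: str  # up | down | unchanged


@dataclass(frozen=True)
class SubpathwayResult:
    """Best-scoring connected subpathway of one pathway with its combined
    Liptak-Stouffer Z and permutation / Bonferroni significance."""

    pathway_id: str
    name: str
    n_measured: int
    best_subgraph: frozenset[str]
    Z: float
    p_perm: float
    p_normal: float
    p_bonferroni: float
    de_count: int
    total_count: int


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric over-representation of DE genes in one gene set."""

    pathway_id: str
    de_count: int
    pathway_size: int
    background_de: int
    background_size: int
    p_hyper: float
    p_adjusted: float

    @property
    def de_over_all(self) -> str:
        return f"{self.de_count}/{self.pathway_size}"


@dataclass(frozen=True)
class SplicingIndexRecord:
    """Per-exon splicing-index contrast between conditions.

    ``si`` is log2(ratio_treated / ratio_control) of exon/gene signal ratios;
    ``fold`` = 2**|si| >= 1 regardless of direction.
    """

    gene: str
    exon_id: str
    ratio_control: float
    ratio_treated: float
    si: float
    fold: float
    direction: str  # reduced | increased | unchanged
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class TopTableRecord:
    """One row of the cross-experiment ranked gene table."""

    gene: str
    p_a: float
    fold_a: float
    p_b: float
    fold_b: float


@dataclass
class AlignmentReport:
    """Venn-style partition of significant genes and pathways between two
    experiments, plus the ranked top table over the union."""

    shared_genes: frozenset[str]
    unique_to_a: frozenset[str]
    unique_to_b: frozenset[str]
    shared_pathways: frozenset[str]
    unique_pathways_a: frozenset[str]
    unique_pathways_b: frozenset[str]
    top_table: list[TopTableRecord] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic generators."""

    de_genes: dict[str, float] = field(default_factory=dict)
    perturbed_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    spliced_exons: dict[tuple[str, str], float] = field(default_factory=dict)
    rng_seed: int = 0

    def to_jsonable(self) -> dict:
        return {
            "rng_seed": self.rng_seed,
            "de_genes": dict(sorted(self.de_genes.items())),
            "perturbed_pathways": {
                k: sorted(v) for k, v in sorted(self.perturbed_pathways.items())
            },
            "spliced_exons": {
                f"{g}::{e}": f for (g, e), f in sorted(self.spliced_exons.items())
            },
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SyntheticTruth":
        return cls(
            de_genes=dict(d.get("de_genes", {})),
            perturbed_pathways={
                k: frozenset(v) for k, v in d.get("perturbed_pathways", {}).items()
            },
            spliced_exons={
                tuple(k.split("::", 1)): f for k, f in d.get("spliced_exons", {}).items()
            },
            rng_seed=int(d.get("rng_seed", 0)),
        )


def signed_z_from_p(p: float, sign: float) -> float:
    """Two-sided p -> signed z: sign * inverse-normal(1 - p/2).

    p = 1 maps to 0; p = 0 (degenerate zero-variance case) is clamped to
    +/- Z_DEGENERATE since the inverse normal diverges.
    """
    from scipy.stats import norm

    if p >= 1.0:
        return 0.0
    if p <= 0.0:
        return math.copysign(Z_DEGENERATE, sign if sign != 0 else 1.0)
    z = float(norm.isf(p / 2.0))
    return math.copysign(z, sign if sign != 0 else 1.0)
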