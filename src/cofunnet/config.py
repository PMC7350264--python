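"""Configuration objects for the synthetic-data generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

EXPERIMENTAL_CODES = ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP")
NON_EXPERIMENTAL_CODES = ("IEA",)
NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

DEFAULT_MAX_LEVEL = {
    "biological_process": 10,
    "cellular_component": 10,
    "molecular_function": 6,
}


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise InvalidConfigError(message)


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth generator.

    The generator emulates a bait–prey AP-MS screen over a universe of
    proteins organised into protein complexes, together with a small GO-style
    ontology, annotations with evidence codes, canonical/splice proteoform
    pairs, and a masked "uncharacterized" (uPE1) protein subset.

    Parameters
    ----------
    n_proteins:
        Size of the canonical protein universe (one gene per protein).
    n_complexes, complex_size_range:
        Number of planted complexes and the inclusive range their sizes are
        drawn from (uniformly).
    overlap_fraction:
        Probability that a complex slot is filled with a protein that already
        belongs to one other complex (proteins join at most two complexes).
    background_fraction:
        Fraction of the universe reserved as complex-free background from
        which contaminants are drawn.
    n_baits:
        Number of distinct baits sampled from complex members; ``None`` baits
        every complex member.
    n_replicates:
        Purifications performed per bait.
    fn_rate:
        Probability that a true complex co-member is missed in a purification.
    fp_rate:
        Expected number of background contaminants per purification
        (Poisson mean).
    n_go_terms_per_namespace, dag_depth:
        Size and depth of each namespace's term DAG (root at level 0).
    annotation_rate:
        Background probability of annotating a (protein, leaf term) pair.
    signature_terms_per_complex, signature_annotation_prob:
        Each complex draws this many leaf "signature" terms per namespace;
        members carry each signature term with this probability, which makes
        network proximity informative about function.
    experimental_fraction:
        Probability that an annotation carries an experimental evidence code
        (uniform over EXP/IDA/IPI/IMP/IGI/IEP); otherwise IEA.
    n_proteoform_genes, proteoform_divergence:
        Number of genes given an alternative splice form, and the fraction of
        the canonical form's complex memberships resampled for the splice
        form.
    master_fraction:
        Fraction of complex-member genes whose appearances are recorded as an
        unresolved "master form" accession instead of the canonical one.
    upe1_fraction:
        Fraction of annotated proteins whose annotations are masked
        (the planted uPE1 set).
    seed:
        RNG seed; a fixed seed makes every artifact byte-identical.
    """

    n_proteins: int = 250
    n_complexes: int = 40
    complex_size_range: tuple[int, int] = (3, 6)
    overlap_fraction: float = 0.1
    background_fraction: float = 0.2
    n_baits: int | None = None
    n_replicates: int = 2
    fn_rate: float = 0.1
    fp_rate: float = 0.5
    n_go_terms_per_namespace: int = 25
    dag_depth: int = 4
    annotation_rate: float = 0.02
    signature_terms_per_complex: int = 2
    signature_annotation_prob: float = 0.9
    experimental_fraction: float = 0.7
    n_proteoform_genes: int = 10
    proteoform_divergence: float = 0.5
    master_fraction: float = 0.1
    upe1_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.complex_size_range, list):
            self.complex_size_range = tuple(self.complex_size_range)
        for name in (
            "fn_rate",
            "overlap_fraction",
            "background_fraction",
            "annotation_rate",
            "signature_annotation_prob",
            "experimental_fraction",
            "proteoform_divergence",
            "master_fraction",
            "upe1_fraction",
        ):
            value = getattr(self, name)
            _check(0.0 <= value <= 1.0, f"{name} must lie in [0, 1], got {value}")
        _check(self.fp_rate >= 0.0, "fp_rate (Poisson mean) must be non-negative")
        lo, hi = self.complex_size_range
        _check(lo >= 2, f"complex_size_range.min must be >= 2, got {lo}")
        _check(hi >= lo, "complex_size_range must be (min, max) with max >= min")
        _check(
            hi <= self.n_proteins,
            f"complex_size_range.max ({hi}) exceeds n_proteins ({self.n_proteins})",
        )
        _check(self.n_complexes >= 0, "n_complexes must be non-negative")
        _check(self.dag_depth >= 1, f"dag_depth must be >= 1, got {self.dag_depth}")
        _check(self.n_go_terms_per_namespace >= self.dag_depth,
               "n_go_terms_per_namespace must be >= dag_depth (one term per level)")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(self.seed >= 0, "seed must be a non-negative integer")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise InvalidConfigError(f"unknown simulation keys: {', '.join(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["complex_size_range"] = list(self.complex_size_range)
        return d


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (validated before any stage runs)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    metric: str = "dice"
    quantile_grid_size: int = 99
    evidence_codes: tuple[str, ...] = EXPERIMENTAL_CODES
    min_support: int = 10
    max_level: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MAX_LEVEL))
    level_convention: str = "shortest"
    cost_grid: tuple[float, ...] = tuple(10.0 ** e for e in range(1, -11, -1))
    cost: float | None = None
    train_fraction: float = 0.8
    min_positives: int = 2
    excluded_terms: tuple[str, ...] = ()
    share_threshold: float = 0.5
    # profile filter: strictly more partners than this; the synthetic default
    # is lower than the analysis convention of 10 because planted complexes
    # (sizes 3-6) give members single-digit degrees
    min_partners: int = 2
    hub_min_degree: int = 150
    enrichment_alpha: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.metric in ("dice", "hart"), "metric must be 'dice' or 'hart'")
        _check(self.level_convention in ("shortest", "longest"),
               "level_convention must be 'shortest' or 'longest'")
        _check(0 < self.train_fraction < 1, "train_fraction must lie in (0, 1)")
        _check(self.quantile_grid_size >= 1, "quantile_grid_size must be >= 1")
        _check(self.min_support >= 1, "min_support must be >= 1")
        _check(len(self.cost_grid) >= 1, "cost_grid must be non-empty")
        _check(0.0 <= self.share_threshold <= 1.0, "share_threshold must lie in [0, 1]")
        unknown_ns = sorted(set(self.max_level) - set(NAMESPACES))
        _check(not unknown_ns, f"unknown namespaces in max_level: {unknown_ns}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise InvalidConfigError(f"unknown pipeline keys: {', '.join(unknown)}")
        data = dict(mapping)
        if "simulation" in data and not isinstance(data["simulation"], SimulationConfig):
            data["simulation"] = SimulationConfig.from_mapping(data["simulation"])
        for key in ("cost_grid", "evidence_codes", "excluded_terms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
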