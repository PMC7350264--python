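"""Synthetic AP-MS study generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: proteins organised into (possibly overlapping) complexes, bait–prey
purifications sampling those complexes with false-negative dropout and
Poisson background contamination, a three-namespace term ontology whose leaf
terms are enriched within complexes, canonical/splice proteoform pairs with
controlled complex-membership divergence, unresolved "master form"
identifications, and a masked uncharacterized (uPE1) protein subset whose
annotations are hidden from the visible files but retained for recovery
scoring.

Every stage draws from an RNG seeded by ``(config.seed, stage_index)``, so
stages are individually reproducible and a fixed seed makes every artifact
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    EXPERIMENTAL_CODES,
    NAMESPACES,
    NON_EXPERIMENTAL_CODES,
    InvalidConfigError,
    SimulationConfig,
)
from .ontology import AnnotationSet, GODag
from .types import ProteoformMap, ProteoformRecord, PurificationRecord, PurificationTable

_STAGE = {"complexes": 0, "proteoforms": 1, "purifications": 2, "go": 3, "mask": 4}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


def protein_accession(index: int) -> str:
    return f"P{index:04d}"


def gene_name(index: int) -> str:
    return f"G{index:04d}"


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator (for evaluation only)."""

    complexes: list[frozenset[str]] = field(default_factory=list)
    proteoform_map: ProteoformMap = field(
        default_factory=lambda: ProteoformMap([])
    )
    true_annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    upe1_mask: frozenset[str] = frozenset()
    background: frozenset[str] = frozenset()

    @property
    def complex_members(self) -> set[str]:
        out: set[str] = set()
        for members in self.complexes:
            out.update(members)
        return out

    def complexes_of(self, accession: str) -> list[int]:
        return [k for k, members in enumerate(self.complexes) if accession in members]


def generate_complexes(config: SimulationConfig) -> PlantedTruth:
    """Plant protein complexes over the canonical universe.

    Sizes are uniform on ``complex_size_range``; a slot is refilled with an
    already-assigned protein (overlap, at most two memberships per protein)
    with probability ``overlap_fraction``. A ``background_fraction`` of the
    universe is reserved for complex-free contaminant proteins.
    """
    lo, hi = config.complex_size_range
    if hi > config.n_proteins:
        raise InvalidConfigError("complex_size_range.max exceeds n_proteins")
    rng = _rng(config, "complexes")
    proteins = [protein_accession(i + 1) for i in range(config.n_proteins)]
    shuffled = list(rng.permutation(proteins))
    n_background = int(round(config.background_fraction * config.n_proteins))
    pool = shuffled[: config.n_proteins - n_background]
    unassigned = list(pool)
    once_assigned: list[str] = []
    complexes: list[frozenset[str]] = []
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    for size in sizes:
        members: set[str] = set()
        while len(members) < size:
            reuse_candidates = [p for p in once_assigned if p not in members]
            if (
                reuse_candidates
                and config.overlap_fraction > 0
                and rng.random() < config.overlap_fraction
            ):
                pick = reuse_candidates[rng.integers(len(reuse_candidates))]
                once_assigned.remove(pick)  # now in two complexes: retire
                members.add(pick)
            elif unassigned:
                pick = unassigned.pop(0)
                once_assigned.append(pick)
                members.add(pick)
            elif reuse_candidates:
                pick = reuse_candidates[rng.integers(len(reuse_candidates))]
                once_assigned.remove(pick)
                members.add(pick)
            else:  # pool exhausted entirely; complex stays smaller
                break
        complexes.append(frozenset(members))
    truth = PlantedTruth(complexes=complexes)
    truth.background = frozenset(set(proteins) - truth.complex_members)
    truth.proteoform_map = ProteoformMap(
        ProteoformRecord(gene=gene_name(i + 1), canonical=protein_accession(i + 1))
        for i in range(config.n_proteins)
    )
    return truth


def plant_proteoforms(truth: PlantedTruth, config: SimulationConfig) -> PlantedTruth:
    """Give a sample of complex-member genes an alternative splice form.

    The splice accession inherits the canonical form's complex memberships
    with a ``proteoform_divergence`` fraction (rounded) resampled to other
    complexes; both forms then participate in purifications. A configurable
    fraction of the remaining complex-member genes is flagged as
    master-form-emitting (their appearances are recorded under an
    unresolved accession).
    """
    rng = _rng(config, "proteoforms")
    member_genes = sorted(
        gene for gene, rec in truth.proteoform_map.by_gene.items()
        if truth.complexes_of(rec.canonical)
    )
    if config.n_proteoform_genes > len(member_genes):
        raise InvalidConfigError(
            f"n_proteoform_genes ({config.n_proteoform_genes}) exceeds the "
            f"number of complex-member genes ({len(member_genes)})"
        )
    chosen = sorted(
        rng.choice(member_genes, size=config.n_proteoform_genes, replace=False)
    )
    complexes = [set(members) for members in truth.complexes]
    records: dict[str, ProteoformRecord] = {
        rec.gene: rec for rec in truth.proteoform_map
    }
    for gene in chosen:
        canonical = records[gene].canonical
        splice = f"{canonical}-2"
        memberships = truth.complexes_of(canonical)
        # stochastic rounding keeps E[resampled] = divergence x memberships
        # even for genes in a single complex (exact when the product is
        # integral, e.g. divergence 0.5 of 4 memberships -> exactly 2)
        exact = config.proteoform_divergence * len(memberships)
        n_resample = int(np.floor(exact))
        if rng.random() < exact - n_resample:
            n_resample += 1
        resampled_away = (
            sorted(
                rng.choice(memberships, size=n_resample, replace=False)
            )
            if n_resample
            else []
        )
        kept = [m for m in memberships if m not in resampled_away]
        candidates = [
            k for k in range(len(complexes)) if k not in memberships
        ]
        n_new = min(n_resample, len(candidates))
        new = (
            sorted(rng.choice(candidates, size=n_new, replace=False))
            if n_new
            else []
        )
        for k in kept + new:
            complexes[k].add(splice)
        records[gene] = ProteoformRecord(
            gene=gene, canonical=canonical, splices=(splice,)
        )
    # master-form genes: complex members that did not get a splice form
    master_candidates = [g for g in member_genes if g not in set(chosen)]
    n_master = int(round(config.master_fraction * len(master_candidates)))
    master_genes = (
        sorted(rng.choice(master_candidates, size=n_master, replace=False))
        if n_master
        else []
    )
    for gene in master_genes:
        rec = records[gene]
        records[gene] = ProteoformRecord(
            gene=gene,
            canonical=rec.canonical,
            splices=rec.splices,
            master=f"{rec.canonical}-M",
        )
    truth.complexes = [frozenset(m) for m in complexes]
    truth.proteoform_map = ProteoformMap(records[g] for g in sorted(records))
    return truth


def simulate_purifications(
    truth: PlantedTruth, config: SimulationConfig
) -> PurificationTable:
    """Simulate bait–prey purifications of the planted complexes.

    Each bait (every complex member by default, ``n_replicates`` runs each)
    pulls down the co-members of all its complexes, each retained with
    probability 1 − ``fn_rate``, plus a Poisson(``fp_rate``) number of
    uniform background contaminants. The bait itself is always identified.
    Master-form genes appear under their master accession.
    """
    rng = _rng(config, "purifications")
    members = sorted(truth.complex_members)
    if config.n_baits is None:
        baits = members
    else:
        if config.n_baits > len(members):
            raise InvalidConfigError(
                f"n_baits ({config.n_baits}) exceeds the number of complex "
                f"members ({len(members)})"
            )
        baits = sorted(rng.choice(members, size=config.n_baits, replace=False))
    for bait in baits:
        if bait not in truth.complex_members:
            raise ValueError(f"bait not in the protein universe: {bait}")
    background = sorted(truth.background)
    master_of = {
        rec.canonical: rec.master
        for rec in truth.proteoform_map
        if rec.master is not None
    }
    records = []
    counter = 0
    for bait in baits:
        co_members = set()
        for k in truth.complexes_of(bait):
            co_members.update(truth.complexes[k])
        co_members.discard(bait)
        co_members = sorted(co_members)
        for _ in range(config.n_replicates):
            counter += 1
            kept = {m for m in co_members if rng.random() >= config.fn_rate}
            n_contaminants = int(rng.poisson(config.fp_rate)) if background else 0
            n_contaminants = min(n_contaminants, len(background))
            contaminants = (
                set(rng.choice(background, size=n_contaminants, replace=False))
                if n_contaminants
                else set()
            )
            identified = {bait} | kept | contaminants
            observed = frozenset(master_of.get(acc, acc) for acc in identified)
            records.append(
                PurificationRecord(
                    purification_id=f"AP{counter:05d}",
                    bait=master_of.get(bait, bait),
                    proteins=observed,
                )
            )
    return PurificationTable(records)


_NS_PREFIX = {"biological_process": 1, "molecular_function": 2, "cellular_component": 3}


def generate_go(
    truth: PlantedTruth, config: SimulationConfig
) -> tuple[GODag, AnnotationSet]:
    """Generate a three-namespace term DAG and leaf-level annotations.

    Each namespace is a rooted DAG of depth ``dag_depth``; deepest-level
    terms form the leaf pool. Every complex draws signature leaves per
    namespace and its members carry them with high probability, so complex
    co-members share terms more often than random pairs; every protein also
    picks up background leaf annotations at ``annotation_rate``. Evidence
    codes are experimental with probability ``experimental_fraction``
    (uniform over EXP/IDA/IPI/IMP/IGI/IEP), IEA otherwise. The returned
    annotation set is leaf-level (not yet ancestor-propagated);
    ``truth.true_annotations`` records each protein's propagated term
    closure.
    """
    rng = _rng(config, "go")
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str, str]] = []
    leaves_by_ns: dict[str, list[str]] = {}
    for namespace in NAMESPACES:
        prefix = _NS_PREFIX[namespace]
        counter = 0

        def new_term(level: int) -> str:
            nonlocal counter
            counter += 1
            term_id = f"GO:{prefix}{counter:06d}"
            terms[term_id] = (f"{namespace} term {counter} (L{level})", namespace)
            return term_id

        root = new_term(0)
        n_rest = config.n_go_terms_per_namespace - 1
        depth = config.dag_depth
        weights = np.arange(1, depth + 1, dtype=float)
        raw = weights / weights.sum() * n_rest
        per_level = np.maximum(np.floor(raw).astype(int), 1)
        while per_level.sum() > n_rest:
            per_level[np.argmax(per_level)] -= 1
        per_level[-1] += n_rest - per_level.sum()
        levels: list[list[str]] = [[root]]
        for level in range(1, depth + 1):
            level_terms = [new_term(level) for _ in range(per_level[level - 1])]
            for term_id in level_terms:
                parent = levels[level - 1][rng.integers(len(levels[level - 1]))]
                edges.append((term_id, parent, "is_a"))
                if level > 1 and rng.random() < 0.3:
                    shallow = levels[int(rng.integers(1, level))]
                    second = shallow[rng.integers(len(shallow))]
                    if second != parent:
                        relation = "part_of" if rng.random() < 0.2 else "is_a"
                        edges.append((term_id, second, relation))
            levels.append(level_terms)
        leaves_by_ns[namespace] = levels[depth]
    dag = GODag(terms, edges)

    def draw_evidence() -> str:
        if rng.random() < config.experimental_fraction:
            return EXPERIMENTAL_CODES[rng.integers(len(EXPERIMENTAL_CODES))]
        return NON_EXPERIMENTAL_CODES[rng.integers(len(NON_EXPERIMENTAL_CODES))]

    triples: set[tuple[str, str, str]] = set()
    # complex signature terms: shared leaf functions of co-members
    for members in truth.complexes:
        for namespace in NAMESPACES:
            pool = leaves_by_ns[namespace]
            k = min(config.signature_terms_per_complex, len(pool))
            signature = rng.choice(pool, size=k, replace=False)
            for member in sorted(members):
                for term_id in signature:
                    if rng.random() < config.signature_annotation_prob:
                        triples.add((member, str(term_id), draw_evidence()))
    # background annotation noise over the whole observable universe
    all_proteins = sorted(
        truth.complex_members
        | truth.background
    )
    for protein in all_proteins:
        for namespace in NAMESPACES:
            for term_id in leaves_by_ns[namespace]:
                if rng.random() < config.annotation_rate:
                    triples.add((protein, term_id, draw_evidence()))
    annotations = AnnotationSet(triples, propagated=False)
    propagated = annotations.propagate(dag)
    truth.true_annotations = {
        protein: frozenset(terms_)
        for protein, terms_ in propagated.terms_by_protein.items()
    }
    return dag, annotations


def mask_upe1(
    truth: PlantedTruth, config: SimulationConfig, annotations: AnnotationSet
) -> AnnotationSet:
    """Mask a fraction of annotated complex members as uncharacterized.

    The visible annotation set drops every assignment of the masked
    proteins; the masked identities stay in ``truth.upe1_mask`` for later
    recovery scoring. Masking is restricted to annotated complex members —
    the proteins that actually carry function signal in the network.
    """
    rng = _rng(config, "mask")
    eligible = sorted(
        p
        for p in truth.complex_members
        if truth.true_annotations.get(p)
    )
    n_mask = int(round(config.upe1_fraction * len(eligible)))
    masked = (
        frozenset(rng.choice(eligible, size=n_mask, replace=False))
        if n_mask
        else frozenset()
    )
    truth.upe1_mask = masked
    return AnnotationSet(
        (t for t in annotations.triples if t[0] not in masked),
        propagated=annotations.propagated,
    )


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    config: SimulationConfig
    truth: PlantedTruth
    purifications: PurificationTable
    dag: GODag
    full_annotations: AnnotationSet  # leaf-level, including masked proteins
    annotations: AnnotationSet  # leaf-level, masked proteins removed


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run all generator stages in order under one configuration."""
    if config is None:
        config = SimulationConfig()
    truth = generate_complexes(config)
    truth = plant_proteoforms(truth, config)
    purifications = simulate_purifications(truth, config)
    dag, full_annotations = generate_go(truth, config)
    visible = mask_upe1(truth, config, full_annotations)
    return SyntheticDataset(
        config=config,
        truth=truth,
        purifications=purifications,
        dag=dag,
        full_annotations=full_annotations,
        annotations=visible,
    )
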