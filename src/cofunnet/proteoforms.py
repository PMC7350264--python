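"""Interactome-profile comparison of canonical vs splice proteoforms.

A protein's interactome profile is its set of network partners. Canonical
and alternatively spliced forms of one gene are compared by the fraction of
profile difference (Jaccard distance by default), binned into the exclusive
classes <50% / ≥50% / ≥75% / ≥90%. Proteins with sufficiently many partners
are single-linkage-grouped into functional components whenever their
common-partner fraction exceeds a share threshold, and each component is
screened for enriched function terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .hopfield import PredictionMatrix
from .ontology import AnnotationSet, EnrichedTerm, hypergeometric_enrichment
from .types import ProteoformMap

#: Exclusive divergence bins: [0, 0.5), [0.5, 0.75), [0.75, 0.9), [0.9, 1].
DIVERGENCE_BINS = ("<50%", ">=50%", ">=75%", ">=90%")

#: Component size classes; mini/mid/macro boundaries are configurable
#: (only the 3–7 "micro" class is a fixed convention here).
DEFAULT_SIZE_CLASSES = (
    ("two-protein", 2, 2),
    ("micro", 3, 7),
    ("mini", 8, 50),
    ("mid", 51, 500),
    ("macro", 501, None),
)


@dataclass(frozen=True)
class InteractomeProfile:
    """A protein and its set of network partners."""

    protein: str
    partners: frozenset[str]

    @property
    def degree(self) -> int:
        return len(self.partners)


def extract_profiles(
    network: nx.Graph, min_partners: int = 10
) -> tuple[dict[str, InteractomeProfile], dict[str, InteractomeProfile]]:
    """Interactome profiles for every node, plus the filtered view keeping
    nodes with strictly more than `min_partners` partners."""
    profiles = {
        node: InteractomeProfile(node, frozenset(network.neighbors(node)) - {node})
        for node in network.nodes
    }
    filtered = {p: prof for p, prof in profiles.items() if prof.degree > min_partners}
    return profiles, filtered


def profile_difference(
    profile_a: InteractomeProfile,
    profile_b: InteractomeProfile,
    method: str = "jaccard",
) -> float:
    """Fraction of interactome-profile difference between two proteins.

    Each protein is removed from the other's partner set before comparison
    (a canonical form interacting with its own splice variant should not
    count against their similarity). ``jaccard``: 1 − |A∩B| / |A∪B|;
    ``overlap``: 1 − |A∩B| / min(|A|, |B|).
    """
    a = profile_a.partners - {profile_b.protein}
    b = profile_b.partners - {profile_a.protein}
    if not a and not b:
        raise ValueError("profile difference undefined for two empty partner sets")
    inter = len(a & b)
    if method == "jaccard":
        return 1.0 - inter / len(a | b)
    if method == "overlap":
        smaller = min(len(a), len(b))
        if smaller == 0:
            return 1.0
        return 1.0 - inter / smaller
    raise ValueError("method must be 'jaccard' or 'overlap'")


@dataclass(frozen=True)
class DivergenceRecord:
    gene: str
    canonical: str
    splice: str
    difference: float

    @property
    def bin(self) -> str:
        if self.difference >= 0.9:
            return ">=90%"
        if self.difference >= 0.75:
            return ">=75%"
        if self.difference >= 0.5:
            return ">=50%"
        return "<50%"


def divergence_records(
    network: nx.Graph,
    proteoform_map: ProteoformMap,
    min_partners: int = 10,
    method: str = "jaccard",
) -> list[DivergenceRecord]:
    """Profile-difference records for every canonical/splice pair where both
    forms have strictly more than `min_partners` network partners."""
    profiles, filtered = extract_profiles(network, min_partners)
    records = []
    for gene in proteoform_map.genes_with_splices():
        rec = proteoform_map.by_gene[gene]
        if rec.canonical not in filtered:
            continue
        for splice in rec.splices:
            if splice not in filtered:
                continue
            diff = profile_difference(filtered[rec.canonical], filtered[splice], method)
            records.append(DivergenceRecord(gene, rec.canonical, splice, diff))
    return records


def classify_divergence(records: Iterable[DivergenceRecord]) -> dict[str, int]:
    """Bin divergence records into the exclusive <50%/≥50%/≥75%/≥90% classes;
    returns the one-row count table including the total."""
    counts = {name: 0 for name in DIVERGENCE_BINS}
    total = 0
    for record in records:
        counts[record.bin] += 1
        total += 1
    counts["total"] = total
    return counts


@dataclass
class FunctionalComponent:
    members: frozenset[str]
    size_class: str
    enrichment: list[EnrichedTerm] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def _size_class(
    size: int, classes: Sequence[tuple[str, int, int | None]]
) -> str:
    for name, lo, hi in classes:
        if size >= lo and (hi is None or size <= hi):
            return name
    return "singleton"


def common_partner_fraction(
    profile_a: InteractomeProfile,
    profile_b: InteractomeProfile,
    method: str = "jaccard",
) -> float:
    """Shared-partner fraction (the complement of profile_difference)."""
    return 1.0 - profile_difference(profile_a, profile_b, method)


def build_components(
    profiles: Mapping[str, InteractomeProfile],
    share_threshold: float = 0.5,
    method: str = "jaccard",
    size_classes: Sequence[tuple[str, int, int | None]] = DEFAULT_SIZE_CLASSES,
) -> tuple[list[FunctionalComponent], list[str]]:
    """Single-linkage grouping of profiles sharing partners.

    An edge joins two profiles when their common-partner fraction strictly
    exceeds `share_threshold`; connected components of that graph are the
    functional components, labeled by size class. Profiles joining no
    component are returned separately as singletons.
    """
    graph = nx.Graph()
    graph.add_nodes_from(profiles)
    for a, b in combinations(sorted(profiles), 2):
        if common_partner_fraction(profiles[a], profiles[b], method) > share_threshold:
            graph.add_edge(a, b)
    components = []
    singletons = []
    for members in nx.connected_components(graph):
        if len(members) == 1:
            singletons.extend(members)
            continue
        components.append(
            FunctionalComponent(
                members=frozenset(members),
                size_class=_size_class(len(members), size_classes),
            )
        )
    components.sort(key=lambda c: (-c.size, sorted(c.members)[0]))
    return components, sorted(singletons)


def annotate_components(
    components: Iterable[FunctionalComponent],
    annotations: AnnotationSet,
    reference: Iterable[str],
    alpha: float = 1e-7,
) -> list[FunctionalComponent]:
    """Attach hypergeometric term enrichment (raw p < `alpha`) to each
    component, tested against the full reference protein set."""
    reference = set(reference)
    out = []
    for component in components:
        target = component.members & reference
        enrichment = (
            hypergeometric_enrichment(target, reference, annotations, alpha)
            if target
            else []
        )
        out.append(
            FunctionalComponent(component.members, component.size_class, enrichment)
        )
    return out


def find_hubs(network: nx.Graph, min_degree: int = 150) -> list[str]:
    """Nodes with strictly more than `min_degree` partners, highest first."""
    degrees = dict(network.degree())
    return sorted(
        (node for node, deg in degrees.items() if deg > min_degree),
        key=lambda node: (-degrees[node], node),
    )


@dataclass(frozen=True)
class FormDisagreement:
    gene: str
    namespace: str
    form_a: str
    form_b: str
    only_a: frozenset[str]
    only_b: frozenset[str]


def compare_form_predictions(
    predictions: PredictionMatrix,
    proteoform_map: ProteoformMap,
    exclude: Iterable[str] = (),
) -> tuple[list[FormDisagreement], list[str]]:
    """Per-gene comparison of predicted term sets across proteoforms.

    For every gene with predictions for ≥2 forms, reports the per-namespace
    symmetric difference of positively predicted terms; abstained cells are
    ignored. Genes where one form abstained on every term are excluded and
    returned separately.
    """
    exclude = set(exclude)
    predicted_for = set(predictions.proteins)
    namespaces = sorted(set(predictions.namespaces.values())) or [""]
    disagreements: list[FormDisagreement] = []
    fully_abstained_genes: list[str] = []
    for gene in sorted(proteoform_map.by_gene):
        rec = proteoform_map.by_gene[gene]
        forms = [f for f in (rec.canonical,) + rec.splices if f in predicted_for]
        if len(forms) < 2:
            continue
        if any(
            len(predictions.abstained_terms(f)) == len(predictions.terms)
            for f in forms
        ):
            fully_abstained_genes.append(gene)
            continue
        for form_a, form_b in combinations(forms, 2):
            terms_a = predictions.predicted_terms(form_a, exclude)
            terms_b = predictions.predicted_terms(form_b, exclude)
            for namespace in namespaces:
                if namespace:
                    in_ns = {
                        t
                        for t, ns in predictions.namespaces.items()
                        if ns == namespace
                    }
                    a_ns, b_ns = terms_a & in_ns, terms_b & in_ns
                else:
                    a_ns, b_ns = terms_a, terms_b
                only_a = a_ns - b_ns
                only_b = b_ns - a_ns
                if only_a or only_b:
                    disagreements.append(
                        FormDisagreement(
                            gene=gene,
                            namespace=namespace,
                            form_a=form_a,
                            form_b=form_b,
                            only_a=frozenset(only_a),
                            only_b=frozenset(only_b),
                        )
                    )
    return disagreements, fully_abstained_genes
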