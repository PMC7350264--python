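"""GO DAG handling: term levels, annotation filtering, Wang semantic
similarity, and hypergeometric term enrichment.

The annotation-filtering cascade mirrors the common practice of pruning a
protein→GO assignment table before network-based function prediction:

1. keep only experimentally evidenced assignments,
2. drop terms supported by fewer than ``min_proteins`` proteins,
3. drop terms deeper than a per-namespace level cutoff
   (BP 10, CC 10, MF 6 by default).

Each filter is idempotent and monotone non-increasing in term count, so the
cascade can be applied in any order on a propagated annotation set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import hypergeom

from .config import DEFAULT_MAX_LEVEL, EXPERIMENTAL_CODES

#: Wang (2007) semantic-contribution factors per edge type.
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class GODag:
    """A rooted, namespaced DAG of ontology terms.

    Edges run child → parent and are typed ``is_a`` or ``part_of``. Each
    namespace has exactly one root (level 0).
    """

    def __init__(
        self,
        terms: Mapping[str, tuple[str, str]],
        edges: Iterable[tuple[str, str, str]],
    ):
        """`terms` maps id → (name, namespace); `edges` are
        (child, parent, relation) triples."""
        self.graph = nx.DiGraph()
        self.name: dict[str, str] = {}
        self.namespace: dict[str, str] = {}
        for term_id, (name, namespace) in terms.items():
            self.graph.add_node(term_id)
            self.name[term_id] = name
            self.namespace[term_id] = namespace
        for child, parent, relation in edges:
            if child not in self.name or parent not in self.name:
                raise ValueError(f"edge references unknown term: {child} -> {parent}")
            self.graph.add_edge(child, parent, relation=relation)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")
        self.roots: dict[str, str] = {}
        for term_id in self.graph:
            if self.graph.out_degree(term_id) == 0:
                ns = self.namespace[term_id]
                if ns in self.roots:
                    raise ValueError(f"namespace {ns} has more than one root")
                self.roots[ns] = term_id
        for term_id in self.graph:
            root = self.roots[self.namespace[term_id]]
            if term_id != root and not nx.has_path(self.graph, term_id, root):
                raise ValueError(f"term {term_id} cannot reach its namespace root")
        self._level_cache: dict[str, dict[str, int]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.name

    def __len__(self) -> int:
        return len(self.name)

    def terms(self) -> list[str]:
        return sorted(self.name)

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable upward from `term_id` (excluding itself)."""
        if term_id not in self:
            raise KeyError(f"unknown term: {term_id}")
        return set(nx.descendants(self.graph, term_id))

    def term_level(self, term_id: str, convention: str = "shortest") -> int:
        """Distance from `term_id` up to its namespace root; root is level 0.

        ``convention='shortest'`` (the default, and the common convention in
        GO tooling) uses the shortest directed path over is_a ∪ part_of
        edges; ``'longest'`` uses the longest path.
        """
        if term_id not in self:
            raise KeyError(f"unknown term: {term_id}")
        if convention not in ("shortest", "longest"):
            raise ValueError("convention must be 'shortest' or 'longest'")
        if convention not in self._level_cache:
            self._level_cache[convention] = self._compute_levels(convention)
        return self._level_cache[convention][term_id]

    def _compute_levels(self, convention: str) -> dict[str, int]:
        levels: dict[str, int] = {}
        if convention == "shortest":
            for root in self.roots.values():
                # BFS downward along reversed edges gives min distance to root
                lengths = nx.single_source_shortest_path_length(
                    self.graph.reverse(copy=False), root
                )
                levels.update(lengths)
        else:
            order = list(nx.topological_sort(self.graph))  # children first
            for node in reversed(order):  # roots first
                parents = list(self.graph.successors(node))
                levels[node] = 0 if not parents else 1 + max(levels[p] for p in parents)
        return levels


@dataclass(frozen=True)
class Annotation:
    protein: str
    term: str
    evidence: str


class AnnotationSet:
    """Protein → term assignments with evidence codes.

    Stores (protein, term, evidence_code) triples; `propagated` marks sets
    closed under ancestor propagation (the true-path rule).
    """

    def __init__(
        self,
        triples: Iterable[tuple[str, str, str]],
        propagated: bool = False,
    ):
        self.triples: frozenset[tuple[str, str, str]] = frozenset(triples)
        self.propagated = propagated
        self._by_term: dict[str, set[str]] | None = None
        self._by_protein: dict[str, set[str]] | None = None

    def __len__(self) -> int:
        return len(self.triples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.triples == other.triples

    def __hash__(self) -> int:
        return hash(self.triples)

    @property
    def proteins_by_term(self) -> dict[str, set[str]]:
        if self._by_term is None:
            out: dict[str, set[str]] = defaultdict(set)
            for protein, term, _ in self.triples:
                out[term].add(protein)
            self._by_term = dict(out)
        return self._by_term

    @property
    def terms_by_protein(self) -> dict[str, set[str]]:
        if self._by_protein is None:
            out: dict[str, set[str]] = defaultdict(set)
            for protein, term, _ in self.triples:
                out[protein].add(term)
            self._by_protein = dict(out)
        return self._by_protein

    @property
    def terms(self) -> set[str]:
        return set(self.proteins_by_term)

    @property
    def proteins(self) -> set[str]:
        return set(self.terms_by_protein)

    def support(self, term: str) -> int:
        """Number of distinct proteins annotated with `term`."""
        return len(self.proteins_by_term.get(term, ()))

    def propagate(self, dag: GODag) -> "AnnotationSet":
        """Close the set under ancestor propagation (true-path rule).

        Each propagated assignment inherits the evidence code of the leaf
        assignment it derives from.
        """
        triples = set(self.triples)
        for protein, term, evidence in self.triples:
            for ancestor in dag.ancestors(term):
                triples.add((protein, ancestor, evidence))
        return AnnotationSet(triples, propagated=True)

    def restrict_proteins(self, keep: Iterable[str]) -> "AnnotationSet":
        keep = set(keep)
        return AnnotationSet(
            (t for t in self.triples if t[0] in keep), propagated=self.propagated
        )


def filter_evidence(
    annotations: AnnotationSet,
    allowed_codes: Iterable[str] = EXPERIMENTAL_CODES,
) -> AnnotationSet:
    """Keep only assignments carrying an allowed evidence code."""
    allowed = set(allowed_codes)
    return AnnotationSet(
        (t for t in annotations.triples if t[2] in allowed),
        propagated=annotations.propagated,
    )


def filter_support(annotations: AnnotationSet, min_proteins: int = 10) -> AnnotationSet:
    """Drop terms supported by fewer than `min_proteins` distinct proteins."""
    if min_proteins < 1:
        raise ValueError("min_proteins must be >= 1")
    keep = {t for t, ps in annotations.proteins_by_term.items() if len(ps) >= min_proteins}
    return AnnotationSet(
        (t for t in annotations.triples if t[1] in keep),
        propagated=annotations.propagated,
    )


def term_level(dag: GODag, term: str, convention: str = "shortest") -> int:
    """Level of `term`: path length up to its namespace root (root = 0)."""
    return dag.term_level(term, convention)


def filter_level(
    dag: GODag,
    annotations: AnnotationSet,
    max_level: Mapping[str, int] | None = None,
    convention: str = "shortest",
) -> AnnotationSet:
    """Drop terms strictly deeper than their namespace's level cutoff."""
    cutoffs = dict(DEFAULT_MAX_LEVEL if max_level is None else max_level)
    keep = set()
    for term in annotations.terms:
        if term not in dag:
            raise KeyError(f"annotated term not in ontology: {term}")
        cutoff = cutoffs.get(dag.namespace[term])
        if cutoff is None or dag.term_level(term, convention) <= cutoff:
            keep.add(term)
    return AnnotationSet(
        (t for t in annotations.triples if t[1] in keep),
        propagated=annotations.propagated,
    )


def _svalues(
    dag: GODag, term: str, weights: Mapping[str, float]
) -> dict[str, float]:
    """Semantic contributions of `term`'s ancestor closure to `term` itself.

    S(term) = 1; going upward, S(parent) = max over incoming closure edges of
    edge_weight × S(child). Computed by relaxation in topological order.
    """
    closure = {term} | dag.ancestors(term)
    sub = dag.graph.subgraph(closure)
    s: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):  # children precede parents
        if node not in s:
            continue
        for _, parent, data in sub.out_edges(node, data=True):
            w = weights.get(data["relation"], 0.0)
            candidate = w * s[node]
            if candidate > s.get(parent, 0.0):
                s[parent] = candidate
    return s


def wang_similarity(
    dag: GODag,
    term_a: str,
    term_b: str,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Wang (2007) semantic similarity between two terms of one namespace.

    Contributions decay multiplicatively along is_a (0.8) and part_of (0.6)
    edges; the similarity is the summed contribution of shared ancestors,
    normalised by the two terms' total semantic values. Cross-namespace
    pairs have similarity 0 by definition.
    """
    if weights is None:
        weights = DEFAULT_EDGE_WEIGHTS
    for t in (term_a, term_b):
        if t not in dag:
            raise KeyError(f"unknown term: {t}")
    if dag.namespace[term_a] != dag.namespace[term_b]:
        return 0.0
    if term_a == term_b:
        return 1.0
    sa = _svalues(dag, term_a, weights)
    sb = _svalues(dag, term_b, weights)
    common = sorted(set(sa) & set(sb))  # sorted: reproducible fp summation
    sv_a = sum(sa[t] for t in sorted(sa))
    sv_b = sum(sb[t] for t in sorted(sb))
    return min(1.0, sum(sa[t] + sb[t] for t in common) / (sv_a + sv_b))


def set_similarity(
    dag: GODag,
    set_a: Iterable[str],
    set_b: Iterable[str],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Best-match-average Wang similarity between two term sets.

    For every term, take its best Wang similarity in the other set; average
    over both directions (symmetric by construction).
    """
    terms_a = sorted(set(set_a))
    terms_b = sorted(set(set_b))
    if not terms_a or not terms_b:
        raise ValueError("set similarity is undefined for empty term sets")
    sims = {
        (a, b): wang_similarity(dag, a, b, weights) for a in terms_a for b in terms_b
    }
    forward = sum(max(sims[(a, b)] for b in terms_b) for a in terms_a) / len(terms_a)
    backward = sum(max(sims[(a, b)] for a in terms_a) for b in terms_b) / len(terms_b)
    return 0.5 * (forward + backward)


@dataclass(frozen=True)
class EnrichedTerm:
    term: str
    p_value: float
    target_hits: int
    reference_hits: int


def hypergeometric_enrichment(
    target_set: Iterable[str],
    reference_set: Iterable[str],
    annotations: AnnotationSet,
    alpha: float = 1e-7,
) -> list[EnrichedTerm]:
    """Upper-tail hypergeometric term enrichment of a target protein set.

    For each annotated term, tests whether the target set contains more
    term-carrying proteins than expected when drawing |target| proteins from
    the reference without replacement. Returns terms with raw p < `alpha`,
    most significant first. A raw cutoff is applied (no multiple-testing
    correction) to mirror a fixed significance-level screen; pass the
    Benjamini–Hochberg-adjusted alpha externally if correction is wanted.
    """
    target = set(target_set)
    reference = set(reference_set)
    if not target:
        raise ValueError("target set is empty")
    if not target <= reference:
        raise ValueError("target set must be a subset of the reference set")
    M = len(reference)
    N = len(target)
    results: list[EnrichedTerm] = []
    for term, proteins in sorted(annotations.proteins_by_term.items()):
        n = len(proteins & reference)
        k = len(proteins & target)
        if k == 0 or n == 0:
            continue
        p = float(hypergeom.sf(k - 1, M, n, N))
        if p < alpha:
            results.append(EnrichedTerm(term, p, k, n))
    results.sort(key=lambda e: (e.p_value, e.term))
    return results
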