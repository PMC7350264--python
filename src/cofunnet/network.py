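"""Co-occurrence scoring of AP-MS purification tables and network assembly.

The matrix-model reading of an AP-MS experiment treats every pair of
proteins identified in the same purification — bait–prey and prey–prey
alike — as a candidate interaction. Pair confidence is quantified two ways:

* the Dice coefficient ``D(i, j) = 2q / (2q + r + s)`` over the two
  proteins' purification profiles, where ``q`` counts purifications holding
  both proteins, ``r`` those holding only ``i`` and ``s`` only ``j``;
* an upper-tail hypergeometric p-value (Hart-style) for observing at least
  ``q`` co-occurrences at random given each protein's occurrence count and
  the total number of purifications.

Only pairs with ``q > 0`` are ever materialised (sparse contract).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.stats import hypergeom

from .types import ProteoformMap, PurificationRecord, PurificationTable


class UndefinedScoreError(ValueError):
    """Raised when a score is requested for an all-zero count triple."""


def normalize_forms(
    purifications: PurificationTable, proteoform_map: ProteoformMap
) -> PurificationTable:
    """Replace unresolved master-form accessions by the gene's canonical form.

    Splice accessions are kept distinct; duplicates arising from the
    substitution collapse by set semantics. Master accessions missing from
    the map raise with the full offender list.
    """
    known = proteoform_map.canonical_of
    offenders = sorted(
        {
            acc
            for record in purifications
            for acc in record.proteins
            if acc.endswith("-M") and acc not in known
        }
    )
    if offenders:
        raise ValueError(
            "master accessions without a canonical mapping: " + ", ".join(offenders)
        )
    records = []
    for record in purifications:
        proteins = frozenset(known.get(acc, acc) for acc in record.proteins)
        bait = known.get(record.bait, record.bait)
        records.append(PurificationRecord(record.purification_id, bait, proteins))
    return PurificationTable(records)


@dataclass
class CooccurrenceCounts:
    """Sparse pairwise co-occurrence counts over a purification table.

    ``q[(i, j)]`` (i < j lexicographically) counts purifications containing
    both proteins; ``n[i]`` counts purifications containing protein ``i``;
    ``N`` is the total number of purifications. ``r = n[i] − q`` and
    ``s = n[j] − q`` follow.
    """

    q: dict[tuple[str, str], int] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)
    N: int = 0

    def pair_counts(self, i: str, j: str) -> tuple[int, int, int]:
        """Return (q, r, s) for the unordered pair {i, j}."""
        key = (i, j) if i <= j else (j, i)
        q = self.q.get(key, 0)
        return q, self.n.get(i, 0) - q, self.n.get(j, 0) - q


def count_cooccurrence(purifications: PurificationTable) -> CooccurrenceCounts:
    """Count pairwise co-occurrence across purifications (matrix model).

    Uses a sparse purification × protein incidence matrix; its Gram matrix
    holds all q counts at once. An empty table yields empty counts.
    """
    proteins = sorted(purifications.universe)
    index = {p: k for k, p in enumerate(proteins)}
    if not proteins or purifications.N == 0:
        return CooccurrenceCounts(N=purifications.N)
    rows, cols = [], []
    for r_idx, record in enumerate(purifications):
        for acc in record.proteins:
            rows.append(r_idx)
            cols.append(index[acc])
    incidence = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(purifications.N, len(proteins)),
    )
    gram = (incidence.T @ incidence).tocoo()
    counts = CooccurrenceCounts(N=purifications.N)
    counts.n = {p: 0 for p in proteins}
    for a, b, value in zip(gram.row, gram.col, gram.data):
        if a == b:
            counts.n[proteins[a]] = int(value)
        elif a < b:
            counts.q[(proteins[a], proteins[b])] = int(value)
    return counts


def dice_score(q: int, r: int, s: int) -> float:
    """Dice coefficient 2q / (2q + r + s) of two purification profiles."""
    if min(q, r, s) < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * q + r + s
    if denom == 0:
        raise UndefinedScoreError("Dice score undefined for q = r = s = 0")
    return 2 * q / denom

def hart_score(q: int, n_i: int, n_j: int, N: int) -> float:
    """Upper-tail hypergeometric p-value of co-occurrence.

    P(X ≥ q) for X ~ Hypergeometric(population N, successes n_i, draws n_j):
    the chance two proteins seen in n_i and n_j of N purifications share at
    least q of them by chance. Smaller means stronger interaction evidence.
    """
    if not (0 <= q <= min(n_i, n_j)):
        raise ValueError("q must satisfy 0 <= q <= min(n_i, n_j)")
    if max(n_i, n_j) > N:
        raise ValueError("occurrence counts cannot exceed the number of purifications")
    return float(hypergeom.sf(q - 1, N, n_i, n_j))


@dataclass(frozen=True)
class PairScore:
    i: str
    j: str
    q: int
    r: int
    s: int
    dice: float
    hart_p: float


class ScoredPairSet:
    """Dice and Hart scores for every co-occurring protein pair."""

    def __init__(self, pairs: Iterable[PairScore], N: int):
        self.pairs: list[PairScore] = sorted(pairs, key=lambda p: (p.i, p.j))
        self.N = N

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.i)
            out.add(p.j)
        return out

    def restrict(self, keep: Iterable[str]) -> "ScoredPairSet":
        keep = set(keep)
        return ScoredPairSet(
            (p for p in self.pairs if p.i in keep and p.j in keep), self.N
        )

    def score_array(self, metric: str) -> np.ndarray:
        if metric == "dice":
            return np.array([p.dice for p in self.pairs])
        if metric == "hart":
            return np.array([p.hart_p for p in self.pairs])
        raise ValueError("metric must be 'dice' or 'hart'")


def score_pairs(counts: CooccurrenceCounts) -> ScoredPairSet:
    """Score every pair with q > 0 by Dice and the Hart hypergeometric tail.

    Vectorised over all pairs; the hypergeometric survival function is
    evaluated in one batched call.
    """
    if not counts.q:
        return ScoredPairSet([], counts.N)
    keys = sorted(counts.q)
    q = np.array([counts.q[k] for k in keys], dtype=np.int64)
    n_i = np.array([counts.n[k[0]] for k in keys], dtype=np.int64)
    n_j = np.array([counts.n[k[1]] for k in keys], dtype=np.int64)
    dice = 2.0 * q / (n_i + n_j)  # 2q + r + s == n_i + n_j
    hart = hypergeom.sf(q - 1, counts.N, n_i, n_j)
    pairs = [
        PairScore(i, j, int(qv), int(niv - qv), int(njv - qv), float(dv), float(hv))
        for (i, j), qv, niv, njv, dv, hv in zip(keys, q, n_i, n_j, dice, hart)
    ]
    return ScoredPairSet(pairs, counts.N)


def build_network(
    scores: ScoredPairSet, threshold: float, metric: str = "dice"
) -> nx.Graph:
    """Threshold scored pairs into an undirected weighted PPI network.

    Dice: keep pairs scoring strictly above the threshold. Hart: keep pairs
    with p-value strictly below it. Edge weights always carry the Dice
    score (the quantity downstream propagation consumes).
    """
    if metric not in ("dice", "hart"):
        raise ValueError("metric must be 'dice' or 'hart'")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    graph = nx.Graph()
    graph.graph["metric"] = metric
    graph.graph["threshold"] = threshold
    for pair in scores:
        if pair.i == pair.j:
            continue
        keep = pair.dice > threshold if metric == "dice" else pair.hart_p < threshold
        if keep:
            graph.add_edge(pair.i, pair.j, weight=pair.dice)
    return graph


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    giant_component_size: int
    median_degree: float
    hubs: list[str]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
            "giant_component_size": self.giant_component_size,
            "median_degree": self.median_degree,
            "hubs": list(self.hubs),
        }


def network_stats(network: nx.Graph, hub_min_degree: int = 150) -> NetworkSummary:
    """Summarise a PPI network: components, giant component, degrees, hubs.

    Hubs are nodes with strictly more than `hub_min_degree` partners,
    reported in descending degree order.
    """
    if network.number_of_nodes() == 0:
        return NetworkSummary(0, 0, 0, 0, 0.0, [])
    components = list(nx.connected_components(network))
    degrees = dict(network.degree())
    hubs = sorted(
        (node for node, deg in degrees.items() if deg > hub_min_degree),
        key=lambda node: (-degrees[node], node),
    )
    return NetworkSummary(
        n_nodes=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        n_components=len(components),
        giant_component_size=max(len(c) for c in components),
        median_degree=float(statistics.median(degrees.values())),
        hubs=hubs,
    )


def score_purifications(purifications: PurificationTable) -> ScoredPairSet:
    """Convenience composition: count co-occurrence, then score all pairs."""
    return score_pairs(count_cooccurrence(purifications))
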