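"""Threshold calibration against a gold standard of protein complexes.

A curated complex catalogue is "pairised" under the matrix model: every
unordered within-complex pair is a reference interaction. Candidate
networks obtained at a grid of score-quantile thresholds are compared to
this reference with precision, recall, and F1 = 2TP / (2TP + FP + FN); the
scan reports the full curve, the maximum F1 (Fmax), and the threshold
achieving it.

Quantile thresholding is inclusive of the quantile value itself (ties at
the boundary are kept together, so a scan over a degenerate all-equal score
distribution keeps every pair rather than none). The raw threshold reported
for each quantile is the midpoint between the smallest retained and largest
discarded score, so rebuilding the network with the strict comparison of
:func:`cofunnet.network.build_network` reproduces the scanned pair set
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .network import ScoredPairSet

Pair = frozenset


@dataclass
class GoldStandard:
    """Named reference complexes and their implied co-complex pair set."""

    complexes: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_complexes(
        cls,
        complexes: Mapping[str, Iterable[str]],
        metadata: Mapping[str, Mapping[str, str]] | None = None,
        metadata_filter: Callable[[Mapping[str, str]], bool] | None = None,
    ) -> "GoldStandard":
        """Build from name → member-list, optionally dropping complexes whose
        metadata fails `metadata_filter` (e.g. a disease-comment screen)."""
        kept = {}
        for name, members in complexes.items():
            if metadata_filter is not None:
                if not metadata_filter((metadata or {}).get(name, {})):
                    continue
            kept[name] = frozenset(members)
        return cls(kept)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out.update(members)
        return out

    def pair_set(self) -> set[frozenset]:
        """All unordered within-complex pairs, deduplicated across
        overlapping complexes (the matrix-model reference)."""
        pairs: set[frozenset] = set()
        for members in self.complexes.values():
            for a, b in combinations(sorted(members), 2):
                pairs.add(frozenset((a, b)))
        return pairs

    def restrict(self, keep: Iterable[str]) -> "GoldStandard":
        keep = set(keep)
        return GoldStandard(
            {name: members & keep for name, members in self.complexes.items()}
        )


def restrict_to_shared(
    scores: ScoredPairSet, gold: GoldStandard
) -> tuple[ScoredPairSet, GoldStandard, set[str]]:
    """Restrict scored pairs and gold standard to their shared proteins."""
    shared = {p for pair in scores for p in (pair.i, pair.j)} & gold.proteins
    if not shared:
        raise ValueError(
            "no proteins shared between the scored pairs and the gold standard"
        )
    return scores.restrict(shared), gold.restrict(shared), shared


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.TP + self.FP + self.FN
        return 2 * self.TP / denom if denom else 0.0


def confusion(
    network_pairs: Iterable[frozenset], gold_pairs: Iterable[frozenset]
) -> ConfusionCounts:
    """TP/FP/FN of a predicted pair set against the gold co-complex pairs."""
    predicted = set(network_pairs)
    gold = set(gold_pairs)
    tp = len(predicted & gold)
    return ConfusionCounts(TP=tp, FP=len(predicted) - tp, FN=len(gold) - tp)


@dataclass(frozen=True)
class ScanPoint:
    quantile: float
    threshold: float
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float


@dataclass
class CalibrationResult:
    curve: list[ScanPoint]
    f_max: float
    best_threshold: float
    best_quantile: float
    metric: str
    n_shared_proteins: int

    def to_dict(self) -> dict:
        return {
            "f_max": self.f_max,
            "best_threshold": self.best_threshold,
            "best_quantile": self.best_quantile,
            "metric": self.metric,
            "n_shared_proteins": self.n_shared_proteins,
        }


def default_quantile_grid(size: int = 99) -> np.ndarray:
    """Evenly spaced quantiles strictly inside (0, 1)."""
    return np.linspace(0.0, 1.0, size + 2)[1:-1]


def _strict_threshold(values: np.ndarray, keep_mask: np.ndarray, metric: str) -> float:
    """Raw threshold reproducing `keep_mask` under the strict comparison."""
    kept = values[keep_mask]
    dropped = values[~keep_mask]
    if metric == "dice":  # keep score > t
        upper = kept.min() if kept.size else 1.0
        lower = dropped.max() if dropped.size else 0.0
    else:  # hart: keep p < t
        lower = kept.max() if kept.size else 0.0
        upper = dropped.min() if dropped.size else 1.0
    return float((lower + upper) / 2.0)


def scan_thresholds(
    scores: ScoredPairSet,
    gold: GoldStandard,
    quantile_grid: Sequence[float] | None = None,
    metric: str = "dice",
) -> CalibrationResult:
    """Scan score-quantile thresholds and locate the F1 maximum (Fmax).

    Both inputs are first restricted to their shared proteins. For the Dice
    orientation high scores are good (quantile q keeps scores ≥ the
    q-quantile); for Hart low p-values are good (quantile q keeps p ≤ the
    q-quantile). Ties with the quantile value are retained.
    """
    if metric not in ("dice", "hart"):
        raise ValueError("metric must be 'dice' or 'hart'")
    if quantile_grid is None:
        quantile_grid = default_quantile_grid()
    grid = sorted(set(float(q) for q in quantile_grid))
    if not grid:
        raise ValueError("quantile grid is empty")
    if grid[0] <= 0.0 or grid[-1] >= 1.0:
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    scores_r, gold_r, shared = restrict_to_shared(scores, gold)
    gold_pairs = gold_r.pair_set()
    values = scores_r.score_array(metric)
    pair_ids = [frozenset((p.i, p.j)) for p in scores_r]
    curve: list[ScanPoint] = []
    best: ScanPoint | None = None
    for q in grid:
        cut = float(np.quantile(values, q)) if values.size else 0.0
        keep = values >= cut if metric == "dice" else values <= cut
        threshold = _strict_threshold(values, keep, metric)
        predicted = {pid for pid, k in zip(pair_ids, keep) if k}
        cc = confusion(predicted, gold_pairs)
        point = ScanPoint(
            quantile=q,
            threshold=threshold,
            TP=cc.TP,
            FP=cc.FP,
            FN=cc.FN,
            precision=cc.precision,
            recall=cc.recall,
            f1=cc.f1,
        )
        curve.append(point)
        if best is None or point.f1 > best.f1:
            best = point
    assert best is not None
    return CalibrationResult(
        curve=curve,
        f_max=best.f1,
        best_threshold=best.threshold,
        best_quantile=best.quantile,
        metric=metric,
        n_shared_proteins=len(shared),
    )
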