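"""Cost-sensitive Hopfield label propagation on weighted PPI networks.

One binary, transductive problem is solved per function term. Nodes carry
bipolar neuron values parametrised by an angle α ∈ (0, π/2): positive state
``sin α``, negative state ``−cos α``. The asymmetric magnitudes let the
network compensate for the heavy class imbalance typical of protein
function labels (few positives, many negatives).

The procedure has three steps:

1. unknown nodes receive provisional states, positive in the same
   proportion as the labeled nodes;
2. (α, γ) are learned on the labeled subnetwork: each labeled node *i* is
   summarised by the point ``(P_i, N_i)`` — its total edge weight to
   labeled positives and to labeled negatives — and a finite sweep selects
   the line ``sin α·P − cos α·N − γ = 0`` maximising the F-score of the
   induced classification of the labeled nodes;
3. asynchronous Hopfield dynamics run on the unknown subnetwork with the
   labeled nodes clamped (a constant external field), node *i* turning
   positive exactly when ``Σ_j w_ij x_j − γ − λ > 0``, until a fixed point.

The regularization cost λ enters as an additive penalty on the activation
threshold: larger λ shifts every decision toward the negative state, so the
number of predicted positives is non-increasing in λ. The associated energy
``E(x) = −½ Σ w_ij x_i x_j − Σ_i x_i (field_i − γ − λ)`` (over unknown
nodes) never increases along an update, which guarantees convergence.

Prediction is optional per node: when a term has too few labeled positives,
or a node's equilibrium activation sits within ε of the threshold, the cell
abstains rather than guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import AnnotationSet, GODag

POSITIVE, NEGATIVE, UNKNOWN = 1, 0, -1

#: Regularization-cost grid: 12 decade values from 10 down to 1e-10.
DEFAULT_COST_GRID: tuple[float, ...] = tuple(10.0 ** e for e in range(1, -11, -1))


def _f_score(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> np.ndarray:
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return out


class HopfieldLabelPropagation:
    """Scikit-learn-style transductive classifier on a weighted graph.

    Parameters
    ----------
    cost : float
        Regularization magnitude λ ≥ 0 added to the activation threshold.
    n_alpha, n_gamma : int
        Resolution of the (α, γ) candidate sweep: α on a uniform open grid
        in (0, π/2), γ on quantiles of the projected labeled points.
    max_sweeps : int
        Full asynchronous sweeps before giving up on equilibrium.
    min_positives : int
        Minimum labeled positives required to attempt prediction; below it
        every unknown node abstains.
    abstain_epsilon_scale : float
        Abstain when |activation − threshold| < scale × max row weight sum.
    random_state : int | None
        Seeds the provisional state assignment and the update order.

    Attributes
    ----------
    alpha_, gamma_ : float
        Learned neuron angle and activation threshold.
    training_f1_ : float
        F-score of the learned linear rule on the labeled nodes.
    transduction_ : ndarray of {1, 0, -1}
        Final labels for every node (-1 = abstained); labeled nodes keep
        their given labels.
    states_ : ndarray
        Equilibrium neuron values.
    converged_ : bool
        Whether the dynamics reached a fixed point within ``max_sweeps``.
    n_iter_ : int
        Number of full sweeps executed.
    """

    def __init__(
        self,
        cost: float = 1e-5,
        n_alpha: int = 64,
        n_gamma: int = 129,
        max_sweeps: int = 100,
        min_positives: int = 2,
        abstain_epsilon_scale: float = 1e-8,
        random_state: int | None = None,
        track_energy: bool = False,
    ):
        self.cost = cost
        self.n_alpha = n_alpha
        self.n_gamma = n_gamma
        self.max_sweeps = max_sweeps
        self.min_positives = min_positives
        self.abstain_epsilon_scale = abstain_epsilon_scale
        self.random_state = random_state
        self.track_energy = track_energy

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "cost": self.cost,
            "n_alpha": self.n_alpha,
            "n_gamma": self.n_gamma,
            "max_sweeps": self.max_sweeps,
            "min_positives": self.min_positives,
            "abstain_epsilon_scale": self.abstain_epsilon_scale,
            "random_state": self.random_state,
            "track_energy": self.track_energy,
        }

    def set_params(self, **params) -> "HopfieldLabelPropagation":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- core -------------------------------------------------------------
    def _validate(self, W: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W = np.asarray(W, dtype=float)
        y = np.asarray(y, dtype=int)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be a square adjacency matrix")
        if y.shape != (W.shape[0],):
            raise ValueError("y must have one entry per node")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        if (W < 0).any():
            raise ValueError("W must be non-negative")
        if not np.isin(y, (POSITIVE, NEGATIVE, UNKNOWN)).all():
            raise ValueError("labels must be 1 (positive), 0 (negative) or -1 (unknown)")
        if self.cost < 0:
            raise ValueError("cost must be non-negative")
        W = W.copy()
        np.fill_diagonal(W, 0.0)
        return W, y

    def _learn_params(
        self, W: np.ndarray, y: np.ndarray
    ) -> tuple[float, float, float]:
        """Sweep (α, γ) candidates maximising the labeled-node F-score.

        Ties are broken toward the larger separation margin, then the
        smaller α. Degenerate all-identical point clouds fall back to
        α = π/4 and γ at the median projection.
        """
        labeled = y != UNKNOWN
        pos = y == POSITIVE
        neg = y == NEGATIVE
        P = W[np.ix_(labeled, pos)].sum(axis=1)
        N = W[np.ix_(labeled, neg)].sum(axis=1)
        truth = y[labeled] == POSITIVE
        if np.ptp(P) == 0.0 and np.ptp(N) == 0.0:
            alpha = math.pi / 4
            proj = math.sin(alpha) * P - math.cos(alpha) * N
            gamma = float(np.median(proj))
            preds = proj - gamma > 0
            tp = float((preds & truth).sum())
            f1 = float(
                _f_score(
                    np.array(tp),
                    np.array((preds & ~truth).sum(), dtype=float),
                    np.array((~preds & truth).sum(), dtype=float),
                )
            )
            return alpha, gamma, f1
        alphas = np.linspace(0.0, math.pi / 2, self.n_alpha + 2)[1:-1]
        quantiles = np.linspace(0.0, 1.0, self.n_gamma)
        best = (-1.0, -np.inf, np.inf)  # (f1, margin, alpha); alpha minimised
        best_alpha = best_gamma = 0.0
        best_f1 = 0.0
        for alpha in alphas:
            proj = math.sin(alpha) * P - math.cos(alpha) * N
            gammas = np.quantile(proj, quantiles)
            preds = proj[None, :] - gammas[:, None] > 0  # n_gamma × n_labeled
            tp = (preds & truth[None, :]).sum(axis=1).astype(float)
            fp = (preds & ~truth[None, :]).sum(axis=1).astype(float)
            fn = ((~preds) & truth[None, :]).sum(axis=1).astype(float)
            f1s = _f_score(tp, fp, fn)
            margins = np.abs(proj[None, :] - gammas[:, None]).min(axis=1)
            for g_idx in range(len(gammas)):
                key = (f1s[g_idx], margins[g_idx], -alpha)
                if key > best:
                    best = key
                    best_alpha = float(alpha)
                    best_gamma = float(gammas[g_idx])
                    best_f1 = float(f1s[g_idx])
        return best_alpha, best_gamma, best_f1

    def _initial_states(
        self, y: np.ndarray, alpha: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Provisional bipolar states: labeled nodes clamp to their label,
        unknown nodes are positive in the labeled positive proportion."""
        s_pos, s_neg = math.sin(alpha), -math.cos(alpha)
        x = np.where(y == POSITIVE, s_pos, s_neg)
        unknown_idx = np.flatnonzero(y == UNKNOWN)
        labeled = y != UNKNOWN
        pos_fraction = (y[labeled] == POSITIVE).mean() if labeled.any() else 0.0
        n_pos = int(round(pos_fraction * len(unknown_idx)))
        x[unknown_idx] = s_neg
        if n_pos > 0:
            chosen = rng.choice(unknown_idx, size=n_pos, replace=False)
            x[chosen] = s_pos
        return x

    def fit(self, X, y) -> "HopfieldLabelPropagation":
        """Learn parameters on the labeled subnetwork and relax the unknown
        nodes to an equilibrium.

        Parameters
        ----------
        X : (n, n) array-like
            Symmetric non-negative adjacency (edge weights).
        y : (n,) array-like of {1, 0, -1}
            Node labels; -1 marks unknown nodes to be transduced.
        """
        W, y = self._validate(X, y)
        n = len(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.array([NEGATIVE, POSITIVE])
        n_positives = int((y == POSITIVE).sum())
        unknown_idx = np.flatnonzero(y == UNKNOWN)
        if n_positives < self.min_positives or (y == NEGATIVE).sum() < 1:
            # Too little signal: abstain everywhere rather than guess.
            self.alpha_ = math.pi / 4
            self.gamma_ = 0.0
            self.training_f1_ = float("nan")
            self.states_ = np.zeros(n)
            self.transduction_ = y.copy()
            self.transduction_[unknown_idx] = UNKNOWN
            self.abstained_ = np.isin(np.arange(n), unknown_idx)
            self.converged_ = True
            self.n_iter_ = 0
            self.energy_trace_ = []
            return self
        self.alpha_, self.gamma_, self.training_f1_ = self._learn_params(W, y)
        x = self._initial_states(y, self.alpha_, rng)
        s_pos, s_neg = math.sin(self.alpha_), -math.cos(self.alpha_)
        theta = self.gamma_ + self.cost
        order = rng.permutation(unknown_idx)  # one fixed order, reused per sweep
        activation = W @ x  # maintained incrementally
        track = self.track_energy
        energies: list[float] = []
        if track:
            energies.append(self._energy(W, x, y, theta))
        sweeps = 0
        converged = False
        while sweeps < self.max_sweeps:
            changed = False
            for i in order:
                u = activation[i] - theta
                new = s_pos if u > 0 else s_neg
                if new != x[i]:
                    delta = new - x[i]
                    x[i] = new
                    activation += delta * W[:, i]
                    changed = True
                if track:
                    energies.append(self._energy(W, x, y, theta))
            sweeps += 1
            if not changed:
                converged = True
                break
        self.states_ = x
        self.converged_ = converged
        self.n_iter_ = sweeps
        self.energy_trace_ = energies
        final_u = W @ x - theta
        eps = self.abstain_epsilon_scale * max(float(W.sum(axis=1).max()), 1.0)
        transduction = y.copy()
        abstained = np.zeros(n, dtype=bool)
        for i in unknown_idx:
            if abs(final_u[i]) < eps:
                transduction[i] = UNKNOWN
                abstained[i] = True
            else:
                transduction[i] = POSITIVE if final_u[i] > 0 else NEGATIVE
        self.transduction_ = transduction
        self.abstained_ = abstained
        return self

    @staticmethod
    def _energy(W: np.ndarray, x: np.ndarray, y: np.ndarray, theta: float) -> float:
        """Hopfield energy over the unknown subnetwork with the labeled
        nodes acting as a constant external field."""
        free = y == UNKNOWN
        xf = x[free]
        Wff = W[np.ix_(free, free)]
        field = W[np.ix_(free, ~free)] @ x[~free]
        return float(-0.5 * xf @ Wff @ xf - xf @ (field - theta))

    def predict(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Transduced labels (1/0, -1 = abstained) for the given node
        indices (default: all nodes)."""
        if not hasattr(self, "transduction_"):
            raise RuntimeError("call fit before predict")
        if indices is None:
            return self.transduction_.copy()
        return self.transduction_[np.asarray(indices, dtype=int)]


# ---------------------------------------------------------------------------
# Functional surface over networkx graphs and annotation sets
# ---------------------------------------------------------------------------


def graph_matrix(graph: nx.Graph) -> tuple[np.ndarray, list[str]]:
    """Dense symmetric weight matrix and the sorted node order behind it."""
    nodes = sorted(graph.nodes)
    W = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    return W, nodes


def term_labels(
    nodes: Sequence[str], annotations: AnnotationSet, term: str
) -> np.ndarray:
    """Per-node labels for one term: positive = annotated with the term,
    negative = annotated protein lacking it, unknown = unannotated."""
    by_protein = annotations.terms_by_protein
    y = np.empty(len(nodes), dtype=int)
    positives = annotations.proteins_by_term.get(term, set())
    for k, node in enumerate(nodes):
        if node in positives:
            y[k] = POSITIVE
        elif node in by_protein:
            y[k] = NEGATIVE
        else:
            y[k] = UNKNOWN
    return y


def initialize_states(
    graph: nx.Graph, labels: Mapping[str, int], alpha: float, seed: int | None = None
) -> dict[str, float]:
    """Provisional bipolar states for unknown nodes, positive in the labeled
    proportion; labeled nodes keep their class value."""
    nodes = sorted(graph.nodes)
    y = np.array([labels.get(node, UNKNOWN) for node in nodes])
    model = HopfieldLabelPropagation(random_state=seed)
    x = model._initial_states(y, alpha, np.random.default_rng(seed))
    return dict(zip(nodes, x))


def learn_params(
    graph: nx.Graph, labels: Mapping[str, int], **kwargs
) -> tuple[float, float, float]:
    """Learn (α, γ) on the labeled subnetwork; returns (alpha, gamma,
    training F-score)."""
    W, nodes = graph_matrix(graph)
    y = np.array([labels.get(node, UNKNOWN) for node in nodes])
    if (y == POSITIVE).sum() < 1 or (y == NEGATIVE).sum() < 1:
        raise ValueError("need at least one labeled positive and one labeled negative")
    model = HopfieldLabelPropagation(**kwargs)
    return model._learn_params(W, y)


def predict_term(
    graph: nx.Graph,
    annotations: AnnotationSet,
    term: str,
    cost: float = 1e-5,
    seed: int | None = None,
    **kwargs,
) -> tuple[pd.Series, HopfieldLabelPropagation]:
    """Run the full three-step procedure for one term.

    Returns a Series indexed by the unknown (unannotated) nodes with values
    1.0 (predicted positive), 0.0 (predicted negative) or NaN (abstained),
    together with the fitted model.
    """
    W, nodes = graph_matrix(graph)
    y = term_labels(nodes, annotations, term)
    model = HopfieldLabelPropagation(cost=cost, random_state=seed, **kwargs)
    model.fit(W, y)
    unknown_idx = np.flatnonzero(y == UNKNOWN)
    values = {
        nodes[i]: (float(model.transduction_[i]) if not model.abstained_[i] else np.nan)
        for i in unknown_idx
    }
    column = pd.Series(values, name=term, dtype=float).sort_index()
    return column, model


@dataclass
class PredictionMatrix:
    """Binary protein × term predictions with per-cell abstention.

    ``matrix`` holds 1.0 / 0.0 / NaN (abstained); ``provenance`` records the
    regularization cost, per-term training F-scores and seeds.
    """

    matrix: pd.DataFrame
    namespaces: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def terms(self) -> list[str]:
        return list(self.matrix.columns)

    def predicted_terms(
        self, protein: str, exclude: Iterable[str] = ()
    ) -> set[str]:
        """Terms predicted positive for `protein` (excluding the given
        ubiquitous terms from summaries)."""
        if protein not in self.matrix.index:
            return set()
        row = self.matrix.loc[protein]
        return {t for t, v in row.items() if v == 1.0 and t not in set(exclude)}

    def abstained_terms(self, protein: str) -> set[str]:
        row = self.matrix.loc[protein]
        return {t for t, v in row.items() if pd.isna(v)}

    def n_predicted_positive(self) -> int:
        return int((self.matrix == 1.0).sum().sum())

    def proteins_with_prediction(
        self, namespace: str | None = None, exclude: Iterable[str] = ()
    ) -> set[str]:
        """Proteins carrying ≥1 positive prediction, optionally within one
        namespace and after dropping excluded terms."""
        exclude = set(exclude)
        terms = [
            t
            for t in self.matrix.columns
            if t not in exclude
            and (namespace is None or self.namespaces.get(t) == namespace)
        ]
        if not terms:
            return set()
        mask = (self.matrix[terms] == 1.0).any(axis=1)
        return set(self.matrix.index[mask])


def predict_all(
    graph: nx.Graph,
    annotations: AnnotationSet,
    dag: GODag | None = None,
    cost: float = 1e-5,
    seed: int | None = None,
    min_positives: int = 2,
    **kwargs,
) -> PredictionMatrix:
    """Predict every annotated term for the unannotated nodes of `graph`.

    One binary Hopfield problem is solved per term; terms with fewer than
    `min_positives` labeled positives yield all-abstained columns. Per-term
    seeds are derived deterministically from `seed`.
    """
    W, nodes = graph_matrix(graph)
    by_protein = annotations.terms_by_protein
    unknown = [node for node in nodes if node not in by_protein]
    terms = sorted(annotations.terms)
    columns: dict[str, pd.Series] = {}
    training_f1: dict[str, float] = {}
    base_seed = 0 if seed is None else int(seed)
    for t_idx, term in enumerate(terms):
        y = term_labels(nodes, annotations, term)
        model = HopfieldLabelPropagation(
            cost=cost,
            random_state=(base_seed + 7919 * t_idx) % (2**31),
            min_positives=min_positives,
            **kwargs,
        )
        model.fit(W, y)
        unknown_idx = np.flatnonzero(y == UNKNOWN)
        values = {
            nodes[i]: (
                float(model.transduction_[i]) if not model.abstained_[i] else np.nan
            )
            for i in unknown_idx
        }
        columns[term] = pd.Series(values, dtype=float)
        training_f1[term] = model.training_f1_
    matrix = pd.DataFrame(index=sorted(unknown), columns=terms, dtype=float)
    for term, col in columns.items():
        matrix.loc[col.index, term] = col
    namespaces = (
        {t: dag.namespace[t] for t in terms if t in dag} if dag is not None else {}
    )
    return PredictionMatrix(
        matrix=matrix,
        namespaces=namespaces,
        provenance={
            "cost": cost,
            "seed": seed,
            "per_term_training_f1": training_f1,
        },
    )


def grid_search_cost(
    graph: nx.Graph,
    annotations: AnnotationSet,
    grid: Sequence[float] = DEFAULT_COST_GRID,
    split: float = 0.8,
    seed: int | None = None,
    min_labeled_per_class: int = 2,
    **kwargs,
) -> tuple[float, pd.DataFrame]:
    """Grid search over the regularization cost λ.

    For each cost, hide a (1 − split) fraction of labeled nodes per term,
    transduce them, and score the hidden positives by F1; average across
    terms (terms with fewer than `min_labeled_per_class` labeled nodes in
    either class after the split are excluded from that run's average).
    Splits are re-drawn independently for every (cost, term) evaluation.
    Returns the argmax cost (ties to the smallest cost) and the per-cost
    score table.
    """
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    grid = list(grid)
    if not grid:
        raise ValueError("cost grid is empty")
    W, nodes = graph_matrix(graph)
    terms = sorted(annotations.terms)
    rng = np.random.default_rng(seed)
    rows = []
    for cost in grid:
        f1s = []
        for term in terms:
            y = term_labels(nodes, annotations, term)
            labeled_idx = np.flatnonzero(y != UNKNOWN)
            n_hide = int(round((1 - split) * len(labeled_idx)))
            if n_hide == 0:
                continue
            hidden = rng.choice(labeled_idx, size=n_hide, replace=False)
            y_train = y.copy()
            y_train[hidden] = UNKNOWN
            for cls in (POSITIVE, NEGATIVE):
                if (y_train == cls).sum() < min_labeled_per_class:
                    break
            else:
                model = HopfieldLabelPropagation(
                    cost=cost,
                    random_state=int(rng.integers(2**31)),
                    **kwargs,
                )
                model.fit(W, y_train)
                pred = model.transduction_[hidden]
                truth = y[hidden]
                tp = float(((pred == POSITIVE) & (truth == POSITIVE)).sum())
                fp = float(((pred == POSITIVE) & (truth == NEGATIVE)).sum())
                fn = float(((pred != POSITIVE) & (truth == POSITIVE)).sum())
                denom = 2 * tp + fp + fn
                if denom > 0 or tp > 0:
                    f1s.append(2 * tp / denom if denom else 0.0)
        rows.append(
            {
                "cost": cost,
                "mean_f1": float(np.mean(f1s)) if f1s else 0.0,
                "n_terms": len(f1s),
            }
        )
    table = pd.DataFrame(rows)
    best_idx = table.sort_values(["mean_f1", "cost"], ascending=[False, True]).index[0]
    return float(table.loc[best_idx, "cost"]), table


def majority_vote_baseline(
    graph: nx.Graph, annotations: AnnotationSet, term: str
) -> pd.Series:
    """Unweighted neighbour-majority baseline used for comparison in tests:
    an unknown node is positive when strictly more of its labeled
    neighbours carry the term than lack it."""
    positives = annotations.proteins_by_term.get(term, set())
    annotated = set(annotations.terms_by_protein)
    values = {}
    for node in sorted(graph.nodes):
        if node in annotated:
            continue
        pos = neg = 0
        for nb in graph.neighbors(node):
            if nb in positives:
                pos += 1
            elif nb in annotated:
                neg += 1
        values[node] = 1.0 if pos > neg else 0.0
    return pd.Series(values, name=term, dtype=float).sort_index()
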