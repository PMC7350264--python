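"""Cost-sensitive Hopfield label propagation: learning, dynamics,
abstention, regularization and determinism."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import cofunnet as cf
from cofunnet.hopfield import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    HopfieldLabelPropagation,
    graph_matrix,
    initialize_states,
    learn_params,
    majority_vote_baseline,
    term_labels,
)
from cofunnet.ontology import AnnotationSet


def two_cliques(n=5, w=1.0):
    """Two disconnected complete graphs; returns (W, y) with one unknown
    node per clique and the rest labeled positive / negative."""
    g = nx.Graph()
    for offset, prefix in ((0, "p"), (n, "n")):
        for a in range(n):
            for b in range(a + 1, n):
                g.add_edge(f"{prefix}{a}", f"{prefix}{b}", weight=w)
    W, nodes = graph_matrix(g)
    y = np.empty(len(nodes), dtype=int)
    for k, node in enumerate(nodes):
        if node in ("p0", "n0"):
            y[k] = UNKNOWN
        else:
            y[k] = POSITIVE if node.startswith("p") else NEGATIVE
    return W, y, nodes


def random_instance(rng, n_max=60):
    n = int(rng.integers(10, n_max))
    W = rng.random((n, n)) * (rng.random((n, n)) < 0.2)
    W = np.triu(W, 1)
    W = W + W.T
    y = rng.choice([POSITIVE, NEGATIVE, UNKNOWN], size=n, p=[0.2, 0.5, 0.3])
    y[:2] = [POSITIVE, NEGATIVE]  # guarantee both classes
    return W, y


class TestInitializeStates:
    def test_proportional_rounding(self):
        g = nx.empty_graph(110)
        labels = {i: POSITIVE if i < 1 else NEGATIVE for i in range(10)}
        # 10% labeled positive, 100 unknown -> 10 provisional positives
        states = initialize_states(g, labels, alpha=math.pi / 4, seed=0)
        positives = [
            node
            for node, value in states.items()
            if node not in labels and value > 0
        ]
        assert len(positives) == 10

    def test_no_unknown_nodes(self):
        g = nx.path_graph(3)
        labels = {0: POSITIVE, 1: NEGATIVE, 2: POSITIVE}
        states = initialize_states(g, labels, alpha=math.pi / 4, seed=0)
        assert all(
            (states[n] > 0) == (labels[n] == POSITIVE) for n in g.nodes
        )

    def test_fixed_seed_reproducible(self):
        g = nx.empty_graph(50)
        labels = {i: POSITIVE if i % 3 else NEGATIVE for i in range(10)}
        a = initialize_states(g, labels, alpha=1.0, seed=42)
        b = initialize_states(g, labels, alpha=1.0, seed=42)
        assert a == b


class TestLearnParams:
    def test_separable_cliques_reach_f1_one(self):
        W, y, _ = two_cliques()
        alpha, gamma, f1 = HopfieldLabelPropagation()._learn_params(W, y)
        assert f1 == 1.0

    def test_single_positive_single_negative_distinct_points(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("c", "d", weight=1.0)
        labels = {"a": POSITIVE, "b": POSITIVE, "c": NEGATIVE, "d": NEGATIVE}
        _, _, f1 = learn_params(g, labels)
        assert f1 == 1.0

    def test_uninformative_weights_near_baseline(self):
        """Random labels on a random graph: training F cannot beat the
        all-positive baseline 2p/(1+p) by much (Monte-Carlo over seeds)."""
        rng = np.random.default_rng(7)
        p = 0.3
        excesses = []
        for _ in range(20):
            n = 80
            W = rng.random((n, n)) * 0.5
            W = np.triu(W, 1)
            W = W + W.T
            y = (rng.random(n) < p).astype(int)
            y[0], y[1] = POSITIVE, NEGATIVE
            _, _, f1 = HopfieldLabelPropagation()._learn_params(W, y)
            baseline = 2 * p / (1 + p)
            excesses.append(f1 - baseline)
        assert np.mean(excesses) < 0.15

    def test_degenerate_identical_points_fall_back(self):
        W = np.zeros((4, 4))
        y = np.array([POSITIVE, NEGATIVE, POSITIVE, UNKNOWN])
        alpha, gamma, _ = HopfieldLabelPropagation()._learn_params(W, y)
        assert alpha == pytest.approx(math.pi / 4)
        assert gamma == pytest.approx(0.0)


class TestDynamics:
    def test_unknowns_adopt_their_cliques_label(self):
        W, y, nodes = two_cliques()
        model = HopfieldLabelPropagation(cost=1e-5, random_state=0).fit(W, y)
        states = dict(zip(nodes, model.transduction_))
        assert states["p0"] == POSITIVE
        assert states["n0"] == NEGATIVE
        assert model.converged_

    def test_huge_cost_forces_all_negative(self):
        W, y, nodes = two_cliques()
        model = HopfieldLabelPropagation(cost=1e6, random_state=0).fit(W, y)
        assert model.transduction_[y == UNKNOWN].tolist() == [NEGATIVE, NEGATIVE]

    def test_zero_weight_graph_predicts_negative(self):
        W = np.zeros((6, 6))
        y = np.array([POSITIVE, POSITIVE, NEGATIVE, NEGATIVE, UNKNOWN, UNKNOWN])
        model = HopfieldLabelPropagation(cost=1e-3, random_state=0).fit(W, y)
        assert (model.transduction_[4:] == NEGATIVE).all()

    def test_energy_never_increases_along_updates(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            W, y = random_instance(rng)
            model = HopfieldLabelPropagation(
                cost=1e-3, random_state=3, track_energy=True
            ).fit(W, y)
            energies = np.array(model.energy_trace_)
            assert (np.diff(energies) <= 1e-9).all()

    def test_converges_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            W, y = random_instance(rng)
            model = HopfieldLabelPropagation(cost=1e-5, random_state=5).fit(W, y)
            assert model.converged_

    def test_fixed_seed_identical_transduction(self):
        rng = np.random.default_rng(17)
        W, y = random_instance(rng)
        a = HopfieldLabelPropagation(random_state=9).fit(W, y)
        b = HopfieldLabelPropagation(random_state=9).fit(W, y)
        assert (a.transduction_ == b.transduction_).all()

    def test_cost_monotonicity_of_positive_counts(self):
        rng = np.random.default_rng(19)
        W, y = random_instance(rng, n_max=80)
        counts = []
        for cost in cf.hopfield.DEFAULT_COST_GRID:
            model = HopfieldLabelPropagation(cost=cost, random_state=1).fit(W, y)
            counts.append(int((model.transduction_[y == UNKNOWN] == POSITIVE).sum()))
        # grid runs from the largest cost down: counts must not decrease
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestAbstention:
    def test_no_labeled_positives_abstains_everywhere(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        ann = AnnotationSet([(0, "t2", "EXP"), (1, "t2", "EXP")])
        column, model = cf.predict_term(g, ann, "t1", seed=0)
        assert column.isna().all()
        assert math.isnan(model.training_f1_)

    def test_sklearn_param_round_trip(self):
        model = HopfieldLabelPropagation(cost=0.5)
        params = model.get_params()
        clone = HopfieldLabelPropagation().set_params(**params)
        assert clone.get_params() == params
        with pytest.raises(ValueError):
            model.set_params(not_a_param=1)


class TestPredictAll:
    def test_empty_term_set_gives_empty_matrix(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        pm = cf.predict_all(g, AnnotationSet([]), seed=0)
        assert pm.matrix.shape[1] == 0

    def test_matrix_shape_and_cell_states(
        self, calibrated_network, filtered_annotations, default_dataset
    ):
        _, _, network = calibrated_network
        pm = cf.predict_all(
            network, filtered_annotations, dag=default_dataset.dag, seed=0
        )
        unknown = [
            n
            for n in network.nodes
            if n not in filtered_annotations.terms_by_protein
        ]
        assert pm.matrix.shape == (len(unknown), len(filtered_annotations.terms))
        values = pm.matrix.values.ravel()
        assert all(v in (0.0, 1.0) or pd.isna(v) for v in values)

    def test_same_seed_identical_matrix(self, calibrated_network, filtered_annotations):
        _, _, network = calibrated_network
        a = cf.predict_all(network, filtered_annotations, cost=1e-5, seed=3)
        b = cf.predict_all(network, filtered_annotations, cost=1e-5, seed=3)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)

    def test_excluded_terms_left_out_of_summaries(
        self, calibrated_network, filtered_annotations
    ):
        _, _, network = calibrated_network
        pm = cf.predict_all(network, filtered_annotations, cost=1e-5, seed=3)
        term = pm.terms[0]
        with_term = pm.proteins_with_prediction()
        without = pm.proteins_with_prediction(exclude=[term])
        assert without <= with_term


class TestGridSearch:
    def test_single_value_grid_returned(self, calibrated_network, filtered_annotations):
        _, _, network = calibrated_network
        best, table = cf.grid_search_cost(
            network, filtered_annotations, grid=[1e-4], seed=0
        )
        assert best == 1e-4 and len(table) == 1

    def test_tie_breaks_to_smallest_cost(self):
        # a signal-free graph scores 0 for every cost: smallest returned
        g = nx.empty_graph(30)
        ann = AnnotationSet(
            [(i, "t", "EXP") for i in range(10)]
            + [(i, "u", "EXP") for i in range(10, 20)]
        )
        best, table = cf.grid_search_cost(g, ann, grid=[1e-1, 1e-3], seed=0)
        assert best == 1e-3
        assert table["mean_f1"].nunique() == 1

    def test_informative_network_best_cost_at_least_matches_largest(
        self, calibrated_network, filtered_annotations
    ):
        _, _, network = calibrated_network
        grid = [10.0, 1e-5]
        best, table = cf.grid_search_cost(
            network, filtered_annotations, grid=grid, seed=0
        )
        best_f1 = table.loc[table["cost"] == best, "mean_f1"].iloc[0]
        largest_f1 = table.loc[table["cost"] == 10.0, "mean_f1"].iloc[0]
        assert best_f1 >= largest_f1


class TestPlantedRecovery:
    def test_noiseless_complex_aligned_terms_recovered_exactly(self):
        """With disjoint complexes, no noise and deterministic signature
        annotation, unknowns receive exactly their complex's terms."""
        config = cf.SimulationConfig(
            seed=8,
            n_proteins=60,
            n_complexes=6,
            complex_size_range=(5, 6),
            fn_rate=0.0,
            fp_rate=0.0,
            overlap_fraction=0.0,
            annotation_rate=0.0,
            signature_annotation_prob=1.0,
            experimental_fraction=1.0,
            n_proteoform_genes=0,
            master_fraction=0.0,
            upe1_fraction=0.2,
        )
        ds = cf.simulate_dataset(config)
        scores = cf.score_purifications(ds.purifications)
        net = cf.build_network(scores, 0.5)
        filtered = cf.filter_evidence(ds.annotations.propagate(ds.dag))
        filtered = filtered.restrict_proteins(net.nodes)
        pm = cf.predict_all(net, filtered, dag=ds.dag, cost=1e-5, seed=1)
        leaf_truth = {
            p: {
                t
                for t in terms
                if not list(ds.dag.graph.predecessors(t))
            }
            for p, terms in ds.truth.true_annotations.items()
        }
        checked = 0
        for protein in ds.truth.upe1_mask:
            if protein not in pm.matrix.index:
                continue
            predicted_leaves = {
                t
                for t in pm.predicted_terms(protein)
                if not list(ds.dag.graph.predecessors(t))
            }
            assert predicted_leaves == leaf_truth[protein]
            checked += 1
        assert checked >= 5

    def test_beats_majority_vote_baseline_on_held_out_labels(
        self, calibrated_network, filtered_annotations
    ):
        _, _, network = calibrated_network
        filt = filtered_annotations
        W, nodes = graph_matrix(network)
        rng = np.random.default_rng(1)
        hopfield_f1, baseline_f1 = [], []
        for term in sorted(filt.terms):
            y = term_labels(nodes, filt, term)
            labeled = np.flatnonzero(y != UNKNOWN)
            hidden = rng.choice(
                labeled, size=int(round(0.2 * len(labeled))), replace=False
            )
            y_train = y.copy()
            y_train[hidden] = UNKNOWN
            if (y_train == POSITIVE).sum() < 2 or (y_train == NEGATIVE).sum() < 2:
                continue
            model = HopfieldLabelPropagation(
                cost=1e-5, random_state=int(rng.integers(2**31))
            ).fit(W, y_train)
            hidden_nodes = {nodes[i] for i in hidden}
            ann_train = AnnotationSet(
                (t for t in filt.triples if t[0] not in hidden_nodes),
                propagated=True,
            )
            base = majority_vote_baseline(network, ann_train, term)

            def f1_of(pred):
                truth = y[hidden]
                tp = ((pred == 1) & (truth == POSITIVE)).sum()
                fp = ((pred == 1) & (truth == NEGATIVE)).sum()
                fn = ((pred != 1) & (truth == POSITIVE)).sum()
                denom = 2 * tp + fp + fn
                return 2 * tp / denom if denom else None

            h = f1_of(model.transduction_[hidden])
            b = f1_of(np.array([base.get(nodes[i], 0.0) for i in hidden]))
            if h is not None and b is not None:
                hopfield_f1.append(h)
                baseline_f1.append(b)
        assert len(hopfield_f1) > 20
        assert np.mean(hopfield_f1) > np.mean(baseline_f1)
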