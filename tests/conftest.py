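"""Shared fixtures: toy ontologies and a cached default synthetic study."""

from __future__ import annotations

import pytest

import cofunnet as cf
from cofunnet.ontology import GODag


@pytest.fixture(scope="session")
def toy_dag() -> GODag:
    """Five-term BP DAG plus an MF root, with a chain and a diamond.

    BP structure (child -> parent, all is_a unless noted)::

        root
         |-- child            (level 1)
         |-- A  <--- T        (diamond: T -> A -> root, level(T) = 2 ...
         |-- B  <-- C <-- T    ... or 3 via the B branch; C part_of B)
    """
    terms = {
        "GO:0000001": ("bp root", "biological_process"),
        "GO:0000002": ("child", "biological_process"),
        "GO:0000003": ("A", "biological_process"),
        "GO:0000004": ("B", "biological_process"),
        "GO:0000005": ("C", "biological_process"),
        "GO:0000006": ("T", "biological_process"),
        "GO:0000007": ("mf root", "molecular_function"),
        "GO:0000008": ("mf child", "molecular_function"),
    }
    edges = [
        ("GO:0000002", "GO:0000001", "is_a"),
        ("GO:0000003", "GO:0000001", "is_a"),
        ("GO:0000004", "GO:0000001", "is_a"),
        ("GO:0000005", "GO:0000004", "part_of"),
        ("GO:0000006", "GO:0000003", "is_a"),
        ("GO:0000006", "GO:0000005", "is_a"),
        ("GO:0000008", "GO:0000007", "is_a"),
    ]
    return GODag(terms, edges)


@pytest.fixture(scope="session")
def default_dataset() -> cf.SyntheticDataset:
    """One simulated study under the default conditions (seed 1), shared
    across tests that only read from it."""
    return cf.simulate_dataset(cf.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_dataset() -> cf.SyntheticDataset:
    """Noise-free, non-overlapping study: purifications reproduce the
    planted complexes exactly."""
    config = cf.SimulationConfig(
        seed=3, fn_rate=0.0, fp_rate=0.0, overlap_fraction=0.0
    )
    return cf.simulate_dataset(config)


@pytest.fixture(scope="session")
def calibrated_network(default_dataset):
    """Scores, calibration and thresholded network of the default study."""
    ds = default_dataset
    normalized = cf.normalize_forms(ds.purifications, ds.truth.proteoform_map)
    scores = cf.score_purifications(normalized)
    gold = cf.GoldStandard(
        {f"CPX{k:04d}": members for k, members in enumerate(ds.truth.complexes)}
    )
    calibration = cf.scan_thresholds(scores, gold)
    network = cf.build_network(scores, calibration.best_threshold)
    return scores, calibration, network


@pytest.fixture(scope="session")
def filtered_annotations(default_dataset, calibrated_network):
    """Propagated, evidence/support/level-filtered annotations restricted
    to the calibrated network's nodes."""
    ds = default_dataset
    _, _, network = calibrated_network
    propagated = ds.annotations.propagate(ds.dag)
    filtered = cf.filter_level(
        ds.dag, cf.filter_support(cf.filter_evidence(propagated), 10)
    )
    return filtered.restrict_proteins(network.nodes)
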