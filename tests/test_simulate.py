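"""Planted-truth generator: complexes, purifications, ontology, proteoforms,
masking, and determinism."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import cofunnet as cf
from cofunnet.config import InvalidConfigError
from cofunnet.simulate import PlantedTruth, plant_proteoforms
from cofunnet.types import ProteoformMap, ProteoformRecord


class TestConfigValidation:
    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidConfigError):
            cf.SimulationConfig(fn_rate=1.2)
        with pytest.raises(InvalidConfigError):
            cf.SimulationConfig(proteoform_divergence=-0.1)

    def test_complex_size_min_below_two_rejected(self):
        with pytest.raises(InvalidConfigError):
            cf.SimulationConfig(complex_size_range=(1, 4))

    def test_complex_size_exceeding_universe_rejected(self):
        with pytest.raises(InvalidConfigError):
            cf.SimulationConfig(n_proteins=5, complex_size_range=(3, 10))

    def test_unknown_keys_rejected(self):
        with pytest.raises(InvalidConfigError, match="unknown"):
            cf.SimulationConfig.from_mapping({"n_protein": 10})


class TestGenerateComplexes:
    def test_zero_complexes(self):
        truth = cf.generate_complexes(cf.SimulationConfig(n_complexes=0))
        assert truth.complexes == []

    def test_sizes_within_range(self):
        config = cf.SimulationConfig(n_complexes=50, complex_size_range=(3, 6), seed=2)
        truth = cf.generate_complexes(config)
        assert len(truth.complexes) == 50
        assert all(3 <= len(c) <= 6 for c in truth.complexes)

    def test_background_proteins_in_no_complex(self):
        config = cf.SimulationConfig(seed=2, background_fraction=0.2)
        truth = cf.generate_complexes(config)
        assert len(truth.background) >= 0.2 * config.n_proteins
        assert not truth.background & truth.complex_members

    def test_no_overlap_when_disabled(self):
        config = cf.SimulationConfig(seed=2, overlap_fraction=0.0)
        truth = cf.generate_complexes(config)
        memberships = [len(truth.complexes_of(p)) for p in truth.complex_members]
        assert max(memberships) == 1

    def test_at_most_two_memberships_with_overlap(self):
        config = cf.SimulationConfig(seed=2, overlap_fraction=0.5)
        truth = cf.generate_complexes(config)
        memberships = [len(truth.complexes_of(p)) for p in truth.complex_members]
        assert max(memberships) == 2

    def test_same_seed_identical(self):
        config = cf.SimulationConfig(seed=9)
        assert (
            cf.generate_complexes(config).complexes
            == cf.generate_complexes(config).complexes
        )


class TestSimulatePurifications:
    def test_noiseless_purification_equals_bait_complex(self):
        config = cf.SimulationConfig(
            seed=4, fn_rate=0.0, fp_rate=0.0, overlap_fraction=0.0,
            n_proteoform_genes=0, master_fraction=0.0,
        )
        truth = cf.generate_complexes(config)
        truth = plant_proteoforms(truth, config)
        table = cf.simulate_purifications(truth, config)
        for record in table:
            (k,) = truth.complexes_of(record.bait)
            assert record.proteins == truth.complexes[k]

    def test_total_dropout_leaves_only_bait(self):
        config = cf.SimulationConfig(
            seed=4, fn_rate=1.0, fp_rate=0.0, n_proteoform_genes=0,
            master_fraction=0.0,
        )
        truth = plant_proteoforms(cf.generate_complexes(config), config)
        table = cf.simulate_purifications(truth, config)
        assert all(record.proteins == {record.bait} for record in table)

    def test_bait_always_present(self, default_dataset):
        for record in default_dataset.purifications:
            assert record.bait in record.proteins

    def test_poisson_contaminant_mean(self):
        config = cf.SimulationConfig(
            seed=4, fn_rate=0.0, fp_rate=2.0, n_replicates=6,
            n_proteoform_genes=0, master_fraction=0.0, overlap_fraction=0.0,
        )
        truth = plant_proteoforms(cf.generate_complexes(config), config)
        table = cf.simulate_purifications(truth, config)
        assert table.N >= 1000
        counts = []
        for record in table:
            (k,) = truth.complexes_of(record.bait)
            counts.append(len(record.proteins - truth.complexes[k]))
        se = np.sqrt(2.0 / len(counts))
        assert abs(np.mean(counts) - 2.0) < 3 * se

    def test_too_many_baits_rejected(self):
        config = cf.SimulationConfig(seed=4, n_baits=10_000)
        truth = plant_proteoforms(cf.generate_complexes(config), config)
        with pytest.raises(InvalidConfigError):
            cf.simulate_purifications(truth, config)


class TestGenerateGo:
    def test_no_annotations_at_zero_rates(self):
        config = cf.SimulationConfig(
            seed=4, annotation_rate=0.0, signature_annotation_prob=0.0
        )
        truth = plant_proteoforms(cf.generate_complexes(config), config)
        _, annotations = cf.generate_go(truth, config)
        assert len(annotations) == 0

    def test_true_path_rule(self, default_dataset):
        """Every protein's propagated term closure includes every ancestor
        of each of its terms."""
        ds = default_dataset
        for protein, terms in list(ds.truth.true_annotations.items())[:50]:
            for term in terms:
                assert ds.dag.ancestors(term) <= terms

    def test_three_namespaces_each_rooted(self, default_dataset):
        dag = default_dataset.dag
        assert set(dag.roots) == {
            "biological_process",
            "molecular_function",
            "cellular_component",
        }
        for term in dag.terms():
            assert dag.term_level(term) <= default_dataset.config.dag_depth

    def test_dag_depth_below_one_rejected(self):
        with pytest.raises(InvalidConfigError):
            cf.SimulationConfig(dag_depth=0)

    def test_within_complex_term_sharing_exceeds_background(self, default_dataset):
        """Complex co-members share leaf terms more than cross-complex
        pairs (the signal label propagation relies on)."""
        ds = default_dataset
        leaf_terms = {
            p: {t for t in terms if not list(ds.dag.graph.predecessors(t))}
            for p, terms in ds.truth.true_annotations.items()
        }

        def overlap(a, b):
            ta, tb = leaf_terms.get(a, set()), leaf_terms.get(b, set())
            union = ta | tb
            return len(ta & tb) / len(union) if union else 0.0

        within = [
            overlap(a, b)
            for members in ds.truth.complexes
            for a, b in combinations(sorted(members), 2)
        ]
        rng = np.random.default_rng(0)
        members = sorted(ds.truth.complex_members)
        cross = []
        while len(cross) < len(within):
            a, b = rng.choice(members, size=2, replace=False)
            if not set(ds.truth.complexes_of(a)) & set(ds.truth.complexes_of(b)):
                cross.append(overlap(a, b))
        assert np.mean(within) > np.mean(cross)


class TestPlantProteoforms:
    def _manual_truth(self):
        # one gene (G0001) in four complexes; two spare complexes to
        # resample into
        complexes = [frozenset({"P0001", f"P000{k}"}) for k in range(2, 6)]
        complexes += [frozenset({"P0006", "P0007"}), frozenset({"P0008", "P0009"})]
        truth = PlantedTruth(complexes=list(complexes))
        truth.proteoform_map = ProteoformMap(
            ProteoformRecord(gene=f"G{i:04d}", canonical=f"P{i:04d}")
            for i in range(1, 10)
        )
        return truth

    def test_zero_divergence_preserves_memberships(self):
        config = cf.SimulationConfig(
            seed=4, proteoform_divergence=0.0, n_proteoform_genes=9
        )
        truth = plant_proteoforms(self._manual_truth(), config)
        for gene in truth.proteoform_map.genes_with_splices():
            rec = truth.proteoform_map.by_gene[gene]
            for splice in rec.splices:
                assert truth.complexes_of(splice) == truth.complexes_of(rec.canonical)

    def test_full_divergence_shares_no_complex(self):
        config = cf.SimulationConfig(
            seed=4, proteoform_divergence=1.0, n_proteoform_genes=9
        )
        truth = plant_proteoforms(self._manual_truth(), config)
        for gene in truth.proteoform_map.genes_with_splices():
            rec = truth.proteoform_map.by_gene[gene]
            for splice in rec.splices:
                assert not set(truth.complexes_of(splice)) & set(
                    truth.complexes_of(rec.canonical)
                )

    def test_half_divergence_of_four_memberships_resamples_two(self):
        config = cf.SimulationConfig(
            seed=4, proteoform_divergence=0.5, n_proteoform_genes=9
        )
        truth = plant_proteoforms(self._manual_truth(), config)
        splice = truth.proteoform_map.by_gene["G0001"].splices[0]
        canonical_memberships = set(truth.complexes_of("P0001"))
        splice_memberships = set(truth.complexes_of(splice))
        assert len(splice_memberships) == 4
        assert len(splice_memberships & canonical_memberships) == 2

    def test_too_many_proteoform_genes_rejected(self):
        config = cf.SimulationConfig(seed=4, n_proteoform_genes=100)
        with pytest.raises(InvalidConfigError):
            plant_proteoforms(self._manual_truth(), config)


class TestMaskUpe1:
    def _pipeline_to_mask(self, **kwargs):
        config = cf.SimulationConfig(seed=6, **kwargs)
        truth = plant_proteoforms(cf.generate_complexes(config), config)
        dag, annotations = cf.generate_go(truth, config)
        visible = cf.mask_upe1(truth, config, annotations)
        return truth, annotations, visible

    def test_zero_fraction_masks_nothing(self):
        truth, annotations, visible = self._pipeline_to_mask(upe1_fraction=0.0)
        assert truth.upe1_mask == frozenset()
        assert visible == annotations

    def test_full_fraction_masks_all_complex_members(self):
        truth, annotations, visible = self._pipeline_to_mask(upe1_fraction=1.0)
        assert not {t for t in visible.triples if t[0] in truth.upe1_mask}
        eligible = {
            p for p in truth.complex_members if truth.true_annotations.get(p)
        }
        assert truth.upe1_mask == eligible

    def test_masked_count_is_rounded_fraction(self):
        truth, _, _ = self._pipeline_to_mask(upe1_fraction=0.1)
        eligible = [
            p for p in truth.complex_members if truth.true_annotations.get(p)
        ]
        assert len(truth.upe1_mask) == round(0.1 * len(eligible))

    def test_masked_proteins_never_leak(self, default_dataset):
        ds = default_dataset
        visible_proteins = {t[0] for t in ds.annotations.triples}
        assert not visible_proteins & ds.truth.upe1_mask
        # but they do have ground-truth annotations for recovery scoring
        for protein in ds.truth.upe1_mask:
            assert ds.truth.true_annotations[protein]


def test_fixed_seed_reproduces_artifacts_byte_identically(tmp_path):
    from cofunnet import io

    for sub in ("a", "b"):
        dataset = cf.simulate_dataset(cf.SimulationConfig(seed=123))
        io.write_dataset(dataset, tmp_path / sub)
    for name in (
        "purifications.tsv",
        "go.obo",
        "annotations.tsv",
        "complexes.gmt",
        "proteoforms.tsv",
        "upe1.tsv",
        "truth.json",
    ):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes()
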