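"""End-to-end orchestration: simulate → score → calibrate → filter →
predict → proteoform analysis, with every intermediate artifact persisted
so stages can be re-run individually from files alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import io
from .calibration import scan_thresholds
from .config import NAMESPACES, PipelineConfig
from .hopfield import grid_search_cost, predict_all
from .network import (
    build_network,
    network_stats,
    normalize_forms,
    score_purifications,
)
from .ontology import filter_evidence, filter_level, filter_support
from .proteoforms import (
    annotate_components,
    build_components,
    classify_divergence,
    compare_form_predictions,
    divergence_records,
    extract_profiles,
    find_hubs,
)
from .simulate import simulate_dataset

_STAGE_OFFSETS = {"simulate": 0, "grid_search": 1, "predict": 2}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derivation from the single global seed."""
    return (global_seed * 10007 + _STAGE_OFFSETS[stage] * 7919 + 17) % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Per-stage record counts and provenance of one pipeline run."""

    counts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    wallclock_s: float = 0.0

    def to_dict(self) -> dict:
        # wallclock stays out: persisted reports must be byte-identical
        # across same-seed runs
        return {
            "counts": self.counts,
            "seeds": self.seeds,
            "params": self.params,
        }


def _namespace_overlap(predictions, exclude=()) -> dict[str, int]:
    """Venn-style counts of proteins with ≥1 positive prediction per
    namespace combination."""
    short = {
        "biological_process": "BP",
        "molecular_function": "MF",
        "cellular_component": "CC",
    }
    per_ns = {
        short[ns]: predictions.proteins_with_prediction(ns, exclude)
        for ns in NAMESPACES
    }
    out = {}
    names = sorted(per_ns)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(per_ns[n] for n in combo))
            outside = set.union(
                *(per_ns[n] for n in names if n not in combo), set()
            )
            out["&".join(combo) + "_only"] = len(inside - outside)
            out["&".join(combo)] = len(inside)
    return out


def _upset_table(predictions, exclude=(), max_rows: int = 50) -> pd.DataFrame:
    """Tabular Upset-style summary: distinct predicted term sets and how
    many proteins carry each."""
    counts: dict[str, int] = {}
    for protein in predictions.proteins:
        terms = predictions.predicted_terms(protein, exclude)
        if not terms:
            continue
        key = ",".join(sorted(terms))
        counts[key] = counts.get(key, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_rows]
    return pd.DataFrame(rows, columns=["term_set", "n_proteins"])


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage under one configuration, persisting all
    artifacts into `out_dir` and returning the consistency report."""
    t0 = time.monotonic()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.params = {
        "metric": config.metric,
        "min_support": config.min_support,
        "max_level": dict(config.max_level),
        "share_threshold": config.share_threshold,
        "simulation": config.simulation.to_dict(),
    }
    report.seeds = {
        "global": config.seed,
        "simulation": config.simulation.seed,
        "grid_search": derive_seed(config.seed, "grid_search"),
        "predict": derive_seed(config.seed, "predict"),
    }

    # -- simulate ---------------------------------------------------------
    try:
        dataset = simulate_dataset(config.simulation)
        paths = io.write_dataset(dataset, out_dir)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("simulate", str(exc)) from exc
    report.counts["simulate"] = {
        "n_proteins": config.simulation.n_proteins,
        "n_complexes": len(dataset.truth.complexes),
        "n_purifications": dataset.purifications.N,
        "n_annotations": len(dataset.annotations),
        "n_upe1": len(dataset.truth.upe1_mask),
    }

    # -- co-occurrence scoring -------------------------------------------
    try:
        purifications = io.read_purifications(paths["purifications"])
        proteoform_map = io.read_proteoforms(paths["proteoforms"])
        normalized = normalize_forms(purifications, proteoform_map)
        scores = score_purifications(normalized)
        io.write_scored_pairs(scores, out_dir / "scored_pairs.tsv")
    except Exception as exc:
        raise StageError("build-network", str(exc)) from exc
    report.counts["scoring"] = {
        "n_purifications": normalized.N,
        "n_scored_pairs": len(scores),
    }

    # -- threshold calibration -------------------------------------------
    try:
        gold = io.read_gold_standard(paths["complexes"])
        from .calibration import default_quantile_grid

        calibration = scan_thresholds(
            scores,
            gold,
            default_quantile_grid(config.quantile_grid_size),
            metric=config.metric,
        )
        io.write_calibration(
            calibration, out_dir / "f1_curve.tsv", out_dir / "calibration.json"
        )
        network = build_network(scores, calibration.best_threshold, config.metric)
        io.write_network(network, out_dir / "network.graphml")
    except Exception as exc:
        raise StageError("select-threshold", str(exc)) from exc
    stats = network_stats(network, config.hub_min_degree)
    report.counts["calibration"] = {
        "f_max": calibration.f_max,
        "best_threshold": calibration.best_threshold,
        "best_quantile": calibration.best_quantile,
        "n_shared_proteins": calibration.n_shared_proteins,
    }
    report.counts["network"] = stats.to_dict()

    # -- GO filtering -----------------------------------------------------
    try:
        dag = io.read_obo(paths["obo"])
        annotations = io.read_annotations(paths["annotations"])
        propagated = annotations.propagate(dag)
        by_evidence = filter_evidence(propagated, config.evidence_codes)
        by_support = filter_support(by_evidence, config.min_support)
        filtered = filter_level(
            dag, by_support, config.max_level, config.level_convention
        )
        io.write_annotations(filtered, out_dir / "filtered_annotations.tsv")
    except Exception as exc:
        raise StageError("filter-go", str(exc)) from exc
    report.counts["go_filter"] = {
        "n_terms_propagated": len(propagated.terms),
        "n_terms_evidence": len(by_evidence.terms),
        "n_terms_support": len(by_support.terms),
        "n_terms_level": len(filtered.terms),
    }

    # -- label propagation ------------------------------------------------
    try:
        network = io.read_network(out_dir / "network.graphml")
        graph_annotations = filtered.restrict_proteins(network.nodes)
        if config.cost is None:
            cost, cost_table = grid_search_cost(
                network,
                graph_annotations,
                grid=config.cost_grid,
                split=config.train_fraction,
                seed=derive_seed(config.seed, "grid_search"),
            )
            cost_table.to_csv(out_dir / "cost_grid.tsv", sep="\t", index=False)
        else:
            cost = config.cost
        predictions = predict_all(
            network,
            graph_annotations,
            dag=dag,
            cost=cost,
            seed=derive_seed(config.seed, "predict"),
            min_positives=config.min_positives,
        )
        io.write_predictions(predictions, out_dir / "predictions.tsv")
        provenance = dict(predictions.provenance)
        provenance["grid_searched"] = config.cost is None
        (out_dir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise StageError("predict", str(exc)) from exc
    n_cells = predictions.matrix.size
    n_abstained = int(predictions.matrix.isna().sum().sum())
    report.counts["predictions"] = {
        "cost": cost,
        "n_unknown_proteins": len(predictions.proteins),
        "n_terms": len(predictions.terms),
        "n_cells": int(n_cells),
        "n_positive": predictions.n_predicted_positive(),
        "n_abstained": n_abstained,
        "namespace_overlap": _namespace_overlap(predictions, config.excluded_terms),
    }
    _upset_table(predictions, config.excluded_terms).to_csv(
        out_dir / "term_set_intersections.tsv", sep="\t", index=False
    )

    # -- proteoform analysis ---------------------------------------------
    try:
        records = divergence_records(
            network, proteoform_map, config.min_partners
        )
        table = classify_divergence(records)
        io.write_divergence(records, table, out_dir)
        _, filtered_profiles = extract_profiles(network, config.min_partners)
        components, singletons = build_components(
            filtered_profiles, config.share_threshold
        )
        components = annotate_components(
            components,
            filtered,
            reference=set(network.nodes),
            alpha=config.enrichment_alpha,
        )
        io.write_components(components, out_dir / "components.tsv")
        hubs = find_hubs(network, config.hub_min_degree)
        io.write_hubs(hubs, network, out_dir / "hubs.tsv")
        disagreements, fully_abstained = compare_form_predictions(
            predictions, proteoform_map, config.excluded_terms
        )
        io.write_form_disagreements(
            disagreements, out_dir / "form_disagreements.tsv"
        )
    except Exception as exc:
        raise StageError("proteoforms", str(exc)) from exc
    report.counts["proteoforms"] = {
        "divergence_bins": table,
        "n_components": len(components),
        "n_singleton_profiles": len(singletons),
        "n_hubs": len(hubs),
        "n_disagreeing_gene_pairs": len(
            {(d.gene, d.form_a, d.form_b) for d in disagreements}
        ),
        "n_fully_abstained_genes": len(fully_abstained),
    }

    report.wallclock_s = time.monotonic() - t0
    _check_consistency(report, predictions, network)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "report.md").write_text(_render_report(report))
    return report


def _check_consistency(report: RunReport, predictions, network) -> None:
    predicted = set(predictions.proteins)
    if not predicted <= set(network.nodes):
        raise StageError(
            "report", "predicted proteins are not a subset of network nodes"
        )
    cells = report.counts["predictions"]
    if cells["n_cells"] != cells["n_unknown_proteins"] * cells["n_terms"]:
        raise StageError("report", "prediction cell count mismatch")


def _render_report(report: RunReport) -> str:
    lines = ["# Pipeline run report", ""]
    for stage, counts in report.counts.items():
        lines.append(f"## {stage}")
        lines.append("")
        for key, value in counts.items():
            lines.append(f"- {key}: {value}")
        lines.append("")
    return "\n".join(lines)
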