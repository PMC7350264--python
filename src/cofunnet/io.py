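"""Readers and writers for the pipeline's text artifacts.

Formats: purification tables (TSV, ragged prey columns), a minimal OBO 1.2
subset (via obonet), annotation and proteoform TSVs, GMT complex sets,
GraphML networks (networkx), and JSON ground truth / reports. Writers sort
rows so fixed-seed runs are byte-identical; readers validate schemas and
report offending line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .calibration import CalibrationResult, GoldStandard
from .hopfield import PredictionMatrix
from .network import PairScore, ScoredPairSet
from .ontology import AnnotationSet, GODag
from .proteoforms import DivergenceRecord, FormDisagreement, FunctionalComponent
from .simulate import PlantedTruth, SyntheticDataset
from .types import ProteoformMap, ProteoformRecord, PurificationRecord, PurificationTable


class SchemaError(ValueError):
    """A file failed schema validation; the message names the line."""


# -- purifications ----------------------------------------------------------


def write_purifications(table: PurificationTable, path: str | Path) -> None:
    lines = ["purification_id\tbait_accession\tpreys"]
    for record in table:
        preys = sorted(record.proteins - {record.bait})
        lines.append("\t".join([record.purification_id, record.bait, *preys]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_purifications(path: str | Path) -> PurificationTable:
    records = []
    seen_ids = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["purification_id", "bait_accession"]:
            raise SchemaError(f"{path}: line 1: unexpected purification header")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise SchemaError(
                    f"{path}: line {lineno}: need purification_id and bait"
                )
            pid, bait, *preys = fields
            if pid in seen_ids:
                raise SchemaError(f"{path}: line {lineno}: duplicate id {pid}")
            seen_ids.add(pid)
            preys = [p for p in preys if p]
            records.append(
                PurificationRecord(pid, bait, frozenset(preys) | {bait})
            )
    return PurificationTable(records)


# -- ontology ---------------------------------------------------------------


def write_obo(dag: GODag, path: str | Path) -> None:
    """Minimal OBO 1.2 serialisation (id / name / namespace / is_a /
    relationship: part_of)."""
    blocks = ["format-version: 1.2\nontology: synthetic-go"]
    for term_id in dag.terms():
        lines = [
            "[Term]",
            f"id: {term_id}",
            f"name: {dag.name[term_id]}",
            f"namespace: {dag.namespace[term_id]}",
        ]
        for _, parent, data in sorted(
            dag.graph.out_edges(term_id, data=True), key=lambda e: e[1]
        ):
            if data["relation"] == "is_a":
                lines.append(f"is_a: {parent} ! {dag.name[parent]}")
            else:
                lines.append(
                    f"relationship: {data['relation']} {parent} ! {dag.name[parent]}"
                )
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def read_obo(path: str | Path) -> GODag:
    graph = obonet.read_obo(path)
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str, str]] = []
    for term_id, data in graph.nodes(data=True):
        namespace = data.get("namespace")
        if namespace is None:
            raise SchemaError(f"{path}: term {term_id} has no namespace")
        terms[term_id] = (data.get("name", term_id), namespace)
    for child, parent, relation in graph.edges(keys=True):
        if relation not in ("is_a", "part_of"):
            continue
        edges.append((child, parent, relation))
    return GODag(terms, edges)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    lines = ["protein\tterm\tevidence_code"]
    for protein, term, evidence in sorted(annotations.triples):
        lines.append(f"{protein}\t{term}\t{evidence}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path, propagated: bool = False) -> AnnotationSet:
    triples = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["protein", "term", "evidence_code"]:
            raise SchemaError(f"{path}: line 1: unexpected annotation header")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 or not all(fields):
                raise SchemaError(
                    f"{path}: line {lineno}: expected protein/term/evidence_code"
                )
            triples.append(tuple(fields))
    return AnnotationSet(triples, propagated=propagated)


# -- complexes (GMT) --------------------------------------------------------


def write_gmt(
    complexes: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name in sorted(complexes):
        desc = (descriptions or {}).get(name, "synthetic complex")
        lines.append("\t".join([name, desc, *sorted(complexes[name])]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT lines → name → (description, member set)."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}: line {lineno}: GMT needs name, description and "
                    f"at least one member"
                )
            name, desc, *members = fields
            if name in out:
                raise SchemaError(f"{path}: line {lineno}: duplicate set {name}")
            out[name] = (desc, frozenset(m for m in members if m))
    return out


def read_gold_standard(path: str | Path) -> GoldStandard:
    parsed = read_gmt(path)
    return GoldStandard({name: members for name, (_, members) in parsed.items()})


# -- proteoform map ---------------------------------------------------------


def write_proteoforms(proteoform_map: ProteoformMap, path: str | Path) -> None:
    lines = ["gene\taccession\tform"]
    for rec in sorted(proteoform_map, key=lambda r: r.gene):
        lines.append(f"{rec.gene}\t{rec.canonical}\tcanonical")
        for splice in rec.splices:
            lines.append(f"{rec.gene}\t{splice}\tsplice")
        if rec.master is not None:
            lines.append(f"{rec.gene}\t{rec.master}\tmaster")
    Path(path).write_text("\n".join(lines) + "\n")


def read_proteoforms(path: str | Path) -> ProteoformMap:
    rows: dict[str, dict[str, list[str]]] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["gene", "accession", "form"]:
            raise SchemaError(f"{path}: line 1: unexpected proteoform header")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise SchemaError(
                    f"{path}: line {lineno}: expected gene/accession/form"
                )
            gene, accession, form = fields
            if form not in ("canonical", "splice", "master"):
                raise SchemaError(
                    f"{path}: line {lineno}: form must be canonical/splice/master"
                )
            rows.setdefault(gene, {"canonical": [], "splice": [], "master": []})[
                form
            ].append(accession)
    records = []
    for gene in sorted(rows):
        forms = rows[gene]
        if len(forms["canonical"]) != 1:
            raise SchemaError(
                f"{path}: gene {gene} must have exactly one canonical accession"
            )
        records.append(
            ProteoformRecord(
                gene=gene,
                canonical=forms["canonical"][0],
                splices=tuple(sorted(forms["splice"])),
                master=forms["master"][0] if forms["master"] else None,
            )
        )
    return ProteoformMap(records)


# -- scored pairs and networks ---------------------------------------------


def write_scored_pairs(scores: ScoredPairSet, path: str | Path) -> None:
    lines = ["i\tj\tq\tr\ts\tdice\thart_p"]
    for p in scores:
        lines.append(
            f"{p.i}\t{p.j}\t{p.q}\t{p.r}\t{p.s}\t{p.dice:.10g}\t{p.hart_p:.10g}"
        )
    lines.append(f"# N\t{scores.N}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scored_pairs(path: str | Path) -> ScoredPairSet:
    pairs = []
    N = 0
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["i", "j", "q", "r", "s", "dice", "hart_p"]:
            raise SchemaError(f"{path}: line 1: unexpected scored-pair header")
        for lineno, line in enumerate(handle, start=2):
            if line.startswith("# N\t"):
                N = int(line.rstrip("\n").split("\t")[1])
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise SchemaError(f"{path}: line {lineno}: expected 7 fields")
            i, j, q, r, s, dice, hart_p = fields
            pairs.append(
                PairScore(i, j, int(q), int(r), int(s), float(dice), float(hart_p))
            )
    return ScoredPairSet(pairs, N)


def write_network(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, path, named_key_ids=True)


def read_network(path: str | Path) -> nx.Graph:
    graph = nx.read_graphml(path)
    if graph.is_directed():
        raise SchemaError(f"{path}: PPI networks must be undirected")
    out = nx.Graph()
    for u, v, data in graph.edges(data=True):
        out.add_edge(u, v, weight=float(data.get("weight", 1.0)))
    out.add_nodes_from(graph.nodes)
    out.graph.update(graph.graph)
    return out


# -- calibration ------------------------------------------------------------


def write_calibration(
    result: CalibrationResult, curve_path: str | Path, summary_path: str | Path
) -> None:
    rows = [
        "quantile\tthreshold\tTP\tFP\tFN\tprecision\trecall\tf1"
    ]
    for point in result.curve:
        rows.append(
            f"{point.quantile:.6g}\t{point.threshold:.10g}\t{point.TP}\t{point.FP}"
            f"\t{point.FN}\t{point.precision:.10g}\t{point.recall:.10g}"
            f"\t{point.f1:.10g}"
        )
    Path(curve_path).write_text("\n".join(rows) + "\n")
    Path(summary_path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


# -- predictions ------------------------------------------------------------


def write_predictions(predictions: PredictionMatrix, path: str | Path) -> None:
    lines = ["protein\tterm\tnamespace\tstate"]
    for protein in predictions.proteins:
        for term in predictions.terms:
            value = predictions.matrix.at[protein, term]
            state = "NA" if pd.isna(value) else str(int(value))
            namespace = predictions.namespaces.get(term, "")
            lines.append(f"{protein}\t{term}\t{namespace}\t{state}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> PredictionMatrix:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["protein", "term", "namespace", "state"]
    if list(frame.columns) != expected:
        raise SchemaError(f"{path}: unexpected prediction header")
    bad = ~frame["state"].isin(["1", "0", "NA"])
    if bad.any():
        lineno = int(frame.index[bad][0]) + 2
        raise SchemaError(f"{path}: line {lineno}: state must be 1, 0 or NA")
    values = frame.assign(
        value=frame["state"].map({"1": 1.0, "0": 0.0, "NA": float("nan")})
    )
    matrix = values.pivot(index="protein", columns="term", values="value")
    namespaces = dict(
        frame[["term", "namespace"]].drop_duplicates().itertuples(index=False)
    )
    return PredictionMatrix(matrix=matrix, namespaces=namespaces)


# -- proteoform analysis outputs -------------------------------------------


def write_divergence(
    records: Iterable[DivergenceRecord], table: Mapping[str, int], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    lines = ["gene\tcanonical\tsplice\tdifference\tbin"]
    for rec in sorted(records, key=lambda r: (r.gene, r.splice)):
        lines.append(
            f"{rec.gene}\t{rec.canonical}\t{rec.splice}\t{rec.difference:.10g}"
            f"\t{rec.bin}"
        )
    (out_dir / "divergence.tsv").write_text("\n".join(lines) + "\n")
    header = ["total", "<50%", ">=50%", ">=75%", ">=90%"]
    row = [str(table.get(h if h != "total" else "total", 0)) for h in header]
    (out_dir / "divergence_table.tsv").write_text(
        "\t".join(header) + "\n" + "\t".join(row) + "\n"
    )


def write_components(
    components: Iterable[FunctionalComponent], path: str | Path
) -> None:
    lines = ["size\tsize_class\tenriched_terms\tmembers"]
    for comp in components:
        enriched = ",".join(f"{e.term}:{e.p_value:.3g}" for e in comp.enrichment)
        lines.append(
            f"{comp.size}\t{comp.size_class}\t{enriched}\t"
            + ",".join(sorted(comp.members))
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_hubs(hubs: Iterable[str], network: nx.Graph, path: str | Path) -> None:
    degrees = dict(network.degree())
    lines = ["protein\tdegree"]
    for hub in hubs:
        lines.append(f"{hub}\t{degrees[hub]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_form_disagreements(
    disagreements: Iterable[FormDisagreement], path: str | Path
) -> None:
    lines = ["gene\tnamespace\tform_a\tform_b\tonly_a\tonly_b"]
    for d in disagreements:
        lines.append(
            f"{d.gene}\t{d.namespace}\t{d.form_a}\t{d.form_b}\t"
            + ",".join(sorted(d.only_a))
            + "\t"
            + ",".join(sorted(d.only_b))
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- ground truth -----------------------------------------------------------


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "complexes": [sorted(members) for members in truth.complexes],
        "proteoform_map": [
            {
                "gene": rec.gene,
                "canonical": rec.canonical,
                "splices": list(rec.splices),
                "master": rec.master,
            }
            for rec in sorted(truth.proteoform_map, key=lambda r: r.gene)
        ],
        "true_annotations": {
            protein: sorted(terms)
            for protein, terms in sorted(truth.true_annotations.items())
        },
        "upe1_mask": sorted(truth.upe1_mask),
        "background": sorted(truth.background),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        complexes=[frozenset(m) for m in payload["complexes"]],
        proteoform_map=ProteoformMap(
            ProteoformRecord(
                gene=r["gene"],
                canonical=r["canonical"],
                splices=tuple(r["splices"]),
                master=r["master"],
            )
            for r in payload["proteoform_map"]
        ),
        true_annotations={
            p: frozenset(t) for p, t in payload["true_annotations"].items()
        },
        upe1_mask=frozenset(payload["upe1_mask"]),
        background=frozenset(payload["background"]),
    )


def write_upe1(upe1: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(upe1)) + "\n")


def read_upe1(path: str | Path) -> frozenset[str]:
    return frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Persist every artifact of a simulated study; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "purifications": out_dir / "purifications.tsv",
        "obo": out_dir / "go.obo",
        "annotations": out_dir / "annotations.tsv",
        "complexes": out_dir / "complexes.gmt",
        "proteoforms": out_dir / "proteoforms.tsv",
        "upe1": out_dir / "upe1.tsv",
        "truth": out_dir / "truth.json",
    }
    write_purifications(dataset.purifications, paths["purifications"])
    write_obo(dataset.dag, paths["obo"])
    write_annotations(dataset.annotations, paths["annotations"])
    write_gmt(
        {
            f"CPX{k + 1:04d}": members
            for k, members in enumerate(dataset.truth.complexes)
        },
        paths["complexes"],
    )
    write_proteoforms(dataset.truth.proteoform_map, paths["proteoforms"])
    write_upe1(dataset.truth.upe1_mask, paths["upe1"])
    write_truth(dataset.truth, paths["truth"])
    return paths


_VALIDATORS = {
    "purifications": read_purifications,
    "obo": read_obo,
    "annotations": read_annotations,
    "gmt": read_gmt,
    "proteoforms": read_proteoforms,
    "network": read_network,
    "scored_pairs": read_scored_pairs,
    "predictions": read_predictions,
}


def validate_io(path: str | Path, schema: str):
    """Parse `path` under the named schema, raising SchemaError on any
    malformed record. Returns the parsed artifact."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file does not exist: {path}")
    if schema not in _VALIDATORS:
        raise ValueError(
            f"unknown schema {schema!r}; expected one of {sorted(_VALIDATORS)}"
        )
    return _VALIDATORS[schema](path)
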