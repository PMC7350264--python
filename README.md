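# cofunnet

Predicting functions of uncharacterized proteins from AP-MS bait–prey
co-occurrence networks — including the splice forms of a gene, whose
interactomes (and hence functions) can differ sharply from the canonical
protein's.

## Who this is for

Interactomics and systems-biology groups who have bait–prey identification
tables from affinity-purification mass spectrometry (AP-MS) screens and
want to (a) turn them into a confidence-scored protein–protein interaction
(PPI) network, (b) transfer Gene Ontology (GO) annotations from
characterized proteins to unannotated ones over that network, and (c) ask
whether canonical and alternatively spliced proteoforms of the same gene
occupy different network neighbourhoods. A synthetic-data generator with
planted ground truth makes every stage testable end to end without any
external database.

## The model

**Scoring.** Under the matrix model, every pair of proteins identified in
the same purification (bait–prey and prey–prey alike) is a candidate
interaction. For proteins *i*, *j* the Dice coefficient over their
purification profiles is

    D(i,j) = 2q / (2q + r + s)

where *q* counts purifications containing both proteins, *r* those with
only *i* and *s* those with only *j*. An alternative hypergeometric score
gives the upper-tail probability P(X ≥ q) of observing the co-occurrence by
chance given each protein's occurrence count and the total number of
purifications.

**Calibration.** A gold standard of curated protein complexes is pairised
into co-complex interactions; scanning score-quantile thresholds and
computing F1 = 2TP/(2TP+FP+FN) on the shared protein universe yields the
F1-maximising threshold (Fmax), which defines the network (edges strictly
above the threshold, weighted by Dice score).

**Annotation filtering.** Protein→GO assignments are propagated to
ancestors (true-path rule), then pruned in three idempotent, commuting
steps: experimental evidence codes only (EXP/IDA/IPI/IMP/IGI/IEP); terms
supported by ≥ 10 proteins; terms no deeper than level 10 (BP, CC) or 6
(MF), where a term's level is its shortest path to the namespace root.

**Label propagation.** One binary transductive problem per term is solved
with a cost-sensitive Hopfield network: neuron values sin α (positive) and
−cos α (negative) absorb class imbalance; (α, γ) are learned by maximising
the F-score of the linear rule sin α·P_i − cos α·N_i − γ > 0 on the labeled
nodes, where (P_i, N_i) are node *i*'s total edge weights to labeled
positives/negatives; asynchronous dynamics with the labeled nodes clamped
run to an energy minimum, with a regularization cost λ added to the
activation threshold. Cells can abstain instead of guessing. λ is chosen by
a decade grid search (10¹…10⁻¹⁰) on 80/20 held-out labels. The estimator is
exposed scikit-learn-style as `HopfieldLabelPropagation` (`fit`,
`predict`, `get_params`).

**Proteoforms.** A protein's interactome profile is its partner set;
canonical/splice pairs are compared by Jaccard distance, binned into
<50% / ≥50% / ≥75% / ≥90% divergence classes, and proteins sharing > 50%
of partners are single-linkage-grouped into functional components screened
for hypergeometric term enrichment (raw p < 10⁻⁷).

## Worked example

```bash
cofunnet pipeline --out run/ --seed 1
```

simulates a study (250 proteins, 40 complexes of size 3–6, every complex
member baited twice, 10% prey dropout, 0.5 expected contaminants per
purification, 10% of annotated members masked as "uPE1"), then scores,
calibrates, filters, predicts and analyses proteoforms. The run report
(`run/report.json`) contains, among others:

```
"calibration": {
  "f_max": 0.9975728155339806,
  "best_threshold": 0.3951219512195122,
  ...
},
"network": {
  "n_nodes": 205, "n_edges": 438, "n_components": 28,
  "giant_component_size": 76, "median_degree": 4.0, ...
}
```

meaning the threshold scan found an almost perfectly separating Dice
cutoff (F1 ≈ 0.998 against the planted complexes at Dice ≈ 0.395), and the
resulting network has 205 proteins with a median of 4 partners each —
complexes survive as near-cliques, contaminant edges are largely excluded.
`run/predictions.tsv` then holds one 1/0/NA call per (unannotated protein,
term) pair, and `run/divergence_table.tsv` the proteoform divergence bin
counts.

The same stages are available individually (`cofunnet simulate`,
`build-network`, `select-threshold`, `filter-go`, `predict`,
`proteoforms`) and as library functions; every stage reads and writes only
plain-text artifacts (TSV, OBO, GMT, GraphML, JSON).

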