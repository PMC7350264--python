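# Methods

This note documents the models, parameter choices, and numerical decisions
behind `cofunnet`, and what the synthetic benchmark does and does not show
about real AP-MS data.

## Co-occurrence scoring

Purification records are interpreted under the matrix model: the bait is a
member of its own identified set, and all unordered within-record pairs
(bait–prey and prey–prey) count as co-occurrences. For a pair seen together
in `q` of `N` purifications, with per-protein occurrence counts `n_i`,
`n_j`, the Dice coefficient is `2q / (n_i + n_j)` (equivalently
`2q / (2q + r + s)` with `r = n_i − q`, `s = n_j − q`). Pairs with `q = 0`
are never materialised; downstream consumers treat absence as score 0.

The hypergeometric ("Hart-style") score is the inclusive upper tail
`P(X ≥ q)` for `X ~ Hypergeom(N, n_i, n_j)`. The population is the number
of purifications and the margins are the per-protein occurrence counts —
the simplest faithful parametrisation, validated in the tests against
exhaustive enumeration for all margin combinations with `N ≤ 8`.

Records are counted as given: technical replicates are separate
purifications and are not deduplicated. Master-form accessions (peptide
evidence insufficient to resolve the proteoform) are mapped to the gene's
canonical accession before counting; splice accessions remain distinct
proteins throughout.

## Threshold calibration

The gold-standard complex set is pairised into all unordered within-complex
pairs, deduplicated across overlapping complexes — the matrix-model
reading of "interactions in the reference set". Scores and gold standard
are first restricted to their shared proteins. For each quantile in an
evenly spaced grid (default 99 points in (0,1)), the scan keeps pairs with
score ≥ the quantile value (Dice; ≤ for the hypergeometric p-value) and
computes precision, recall and F1.

Two numerical choices matter here:

* **Ties at the quantile are kept.** Thresholding with a strict comparison
  at the empirical quantile would discard entire tied blocks — in the
  degenerate noiseless limit (all retained scores equal 1) it would discard
  *everything*. Keeping ties makes the scan well-behaved on discrete score
  distributions.
* **The reported raw threshold is a midpoint.** For each quantile the
  curve reports the midpoint between the smallest retained and largest
  discarded score. Network construction uses a strict comparison
  ("greater than the threshold"), so rebuilding with the reported value
  reproduces the scanned pair set exactly. Both the raw threshold and the
  quantile are reported.

## Annotation filtering

Annotations are ancestor-propagated (true-path rule) *before* support
counting; otherwise specific terms are punished twice — once for being
specific, once for their small raw count. Propagated assignments inherit
the evidence code of the leaf assignment they derive from. The cascade
then applies:

1. evidence filter — keep codes in {EXP, IDA, IPI, IMP, IGI, IEP};
2. support filter — drop terms with fewer than 10 distinct proteins
   ("fewer than" is strict: exactly 10 survives);
3. level filter — drop terms with level strictly greater than 10 (BP, CC)
   or 6 (MF).

A term's level is its shortest-path distance to the namespace root over
is_a ∪ part_of edges (root = 0), the common convention in GO tooling; a
longest-path convention is available behind the `level_convention` switch.
All three filters are idempotent and commute pairwise on propagated sets,
which the tests assert.

Wang semantic similarity uses the original semantic-contribution factors
0.8 (is_a) and 0.6 (part_of); S-values are computed by max-product
relaxation in topological order over the ancestor closure, and set-vs-set
similarity is the symmetric best-match average. Identical terms
short-circuit to exactly 1.0, and summations run in sorted key order so
results are bit-reproducible across interpreter hash seeds.

Term enrichment of a protein set against a reference is the inclusive
upper-tail hypergeometric p-value with a raw significance cutoff (default
p < 10⁻⁷, emulating a fixed-significance web-service screen). No
multiple-testing correction is applied by default; Benjamini–Hochberg can
be layered on by adjusting the cutoff externally.

## Cost-sensitive Hopfield label propagation

Each term defines a binary transductive problem on the weighted network:
positives are proteins annotated with the term, negatives are annotated
proteins lacking it, unknowns are unannotated (uPE1/masked) proteins.

Neuron values are `sin α` (positive) and `−cos α` (negative) with
α ∈ (0, π/2); the asymmetric magnitudes let a minority positive class
exert proportionate influence. The labeled subnetwork summarises each
labeled node *i* as the point `(P_i, N_i)` — summed edge weights to
labeled positives and negatives — and (α, γ) are chosen by a finite sweep
(64 uniform α values × 129 γ quantiles of the projected points) maximising
the F-score of `sin α·P_i − cos α·N_i − γ > 0`, with ties broken toward
the larger separation margin, then the smaller α. A uniform sweep replaces
the asymptotically faster ordered sweep of the original cost-sensitive
formulation; at the problem sizes here the dense sweep is simpler and
exactly testable. Degenerate all-identical point clouds fall back to
α = π/4, γ = median projection.

Unknown nodes are initialised with provisional states, positive in the
labeled positive proportion (rounded), then updated asynchronously in one
fixed seeded permutation, reused across sweeps: node *i* turns positive
exactly when `Σ_j w_ij x_j − γ − λ > 0`. Labeled nodes are clamped — they
contribute a constant external field, realising "dynamics on the unlabeled
subnetwork". The energy
`E(x) = −½ Σ w x_i x_j − Σ x_i (field_i − γ − λ)` over unknown nodes is
non-increasing along every update (weights are non-negative and the
diagonal is zeroed), so a fixed point exists and is reached; `max_sweeps`
(default 100) is a safety valve and non-convergence is flagged, never
silent.

**How the cost enters.** The regularization cost λ is an additive penalty
on the activation threshold, shifting every decision toward the negative
state. This reading uses a single scalar as required, and makes the number
of positive predictions provably non-increasing in λ (monotone dynamics
argument, asserted over the full decade grid in the tests). Other
regularizer placements are conceivable; this one is documented as the
package's interpretation.

**Abstention.** A term with fewer than 2 labeled positives yields an
all-abstained column; a node whose equilibrium activation lies within
ε = 10⁻⁸ × (maximum incident weight sum) of the threshold abstains rather
than guess. Both rules are artifact decisions — the contract is only that
prediction is optional per cell.

**Cost selection.** For each λ in {10¹, 10⁰, …, 10⁻¹⁰} and each term, 20%
of labeled nodes are hidden (fresh draw per evaluation), transduced, and
scored by F1 on the hidden positives; per-term F1 values are averaged
jointly across namespaces (per-namespace averaging is available). Terms
left with fewer than 2 labeled nodes in either class are excluded from
that run's average. Ties go to the smallest cost. No hierarchical
consistency is enforced across terms — each column is an independent
problem.

## Proteoform analysis

The interactome profile of a protein is its partner set in the thresholded
network. For a canonical/splice pair, each form is first removed from the
other's partner set (a form interacting with its sibling should not count
as divergence), then the difference is the Jaccard distance
`1 − |A∩B| / |A∪B|`; an overlap-coefficient variant
(`1 − |A∩B| / min(|A|,|B|)`) is selectable, since "percent common
partners" does not name a normalisation. Divergence bins
[0, 0.5), [0.5, 0.75), [0.75, 0.9), [0.9, 1] are exclusive and exhaustive,
so the counts always sum to the pair total.

Functional components connect profiles whose common-partner fraction
strictly exceeds 0.5 and take connected components (single linkage — the
minimal reading of "combined into one group"). Size classes: two-protein
(2), micro (3–7, the one conventional boundary), then mini/mid/macro with
configurable defaults 8–50 / 51–500 / >500; the boundaries are reported
with the output, never baked into it. Hubs are nodes with strictly more
than 150 partners.

Profile comparison conventionally requires strictly more than 10 partners
per form. The synthetic pipeline defaults to `min_partners = 2` because
planted complexes of size 3–6 give members single-digit degrees; the
analysis-facing functions keep 10 as their default.

## The synthetic generator

The generator plants the structure the analysis assumes, at desk scale:

* **Complexes:** 40 complexes, sizes uniform on [3, 6], drawn from a
  250-protein universe with 20% reserved as complex-free background; a
  slot is refilled with an already-assigned protein with probability 0.1
  (overlap; at most two memberships per protein, mirroring the modest
  overlap of curated complex catalogues).
* **Purifications:** every complex member is baited, two replicates each
  (mirroring replicated screens); a purification holds the bait, each
  co-member of the bait's complexes with probability 0.9 (fn_rate = 0.1),
  and a Poisson(0.5) number of uniform background contaminants. The
  background contaminant structure of real screens is unknown; the
  Poisson-uniform model is an explicit assumption.
* **Ontology and annotations:** three namespaces, each a rooted DAG of
  depth 4 with 25 terms, deeper levels wider; ~30% of terms acquire a
  second parent (part_of with probability 0.2). Each complex draws 2
  signature leaves per namespace from the leaf pool — the pool is smaller
  than the complex count, so signatures recur across complexes and term
  support comfortably clears the ≥10 filter. Members carry each signature
  leaf with probability 0.9; every protein also picks up background leaf
  annotations at rate 0.02. Evidence codes are experimental with
  probability 0.7 (uniform over the six codes), IEA otherwise, so the
  evidence filter does real work.
* **Proteoforms:** 10 complex-member genes gain a splice form whose
  complex memberships are the canonical's with a `proteoform_divergence`
  fraction resampled to other complexes. The fractional count is
  stochastically rounded, so the expected resampled fraction equals the
  dial even for single-membership genes while integral products (e.g. half
  of four memberships) stay exact. A further 10% of member genes emit
  master-form accessions to exercise the master→canonical rule.
* **uPE1 mask:** 10% of annotated complex members have all annotations
  hidden from the visible files; their identities and true term closures
  are retained separately for recovery scoring. Masking is restricted to
  complex members because only they carry recoverable network signal — a
  background protein's annotations are noise by construction.

Every stage draws from `default_rng([seed, stage_index])`, so artifacts
are byte-identical under a fixed seed and stages re-run in isolation.

**What passing tests show — and don't.** The benchmark shows the pipeline
recovers planted, network-aligned function signal under moderate dropout
and contamination, and that every contract (filter algebra, energy
descent, λ-monotonicity, determinism) holds. It does not emulate
peptide-level identification error, bait expression artifacts, correlated
contaminants (the CRAPome phenomenon), annotation biases of real GO, or
the scale of a genome-wide screen (thousands of baits, hundreds of
thousands of scored pairs) — headline numbers from real studies are
therefore not comparable to the synthetic run's outputs, and the package
reports structure (rates, correlations, bounds) rather than matching
external counts. Problem sizes throughout (250 proteins, ≤500-node
Hopfield instances, 5-point divergence sweeps) were chosen as the smallest
scales at which every planted effect is comfortably detectable.

## Known limitations

* The Hopfield regularizer placement and the exact quantile convention of
  the threshold scan are documented interpretations of under-specified
  procedures; both are surfaced as explicit, tested choices.
* Enrichment uses a raw p-value cutoff by design; at genome scale a
  corrected procedure is usually preferable.
* GAF qualifiers, obsolete-term/alt-id resolution, and spoke-model scoring
  are out of scope.
* The majority-vote baseline is intentionally simple; it is a floor for
  the propagation, not a competitive alternative.
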