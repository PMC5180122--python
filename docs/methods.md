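# Methods

## The problem

Morphology-based species counts in poorly described faunas — deep-sea
polychaetes are the motivating case — systematically miss *cryptic
species*: lineages that are genetically distinct but morphologically
indistinguishable. Multi-locus DNA-barcode surveys address this by
sequencing two mitochondrial fragments per specimen (the ~660 bp COI
"Folmer" barcode and a ~500 bp stretch of 16S rDNA), grouping each
morphospecies' specimens into genetic clades, and asking whether the
divergence *between* clades is distributionally separate from the
divergence *within* them. `barcodegap` packages that analysis end to
end, together with a sequence simulator that plants known cryptic
structure so every stage can be validated at desk scale.

## Distance model

Pairwise divergence is estimated under Kimura's two-parameter (K2P)
substitution model. With P and Q the proportions of compared sites
differing by a transition and a transversion,

    d = -(1/2) ln[(1 - 2P - Q) sqrt(1 - 2Q)] .

Sites where either sequence carries a gap, an N or any IUPAC ambiguity
code are excluded per pair (*pairwise deletion*), which maximises
usable data for specimens with ragged sequence ends; the number of
comparable sites is kept per cell. Pairs with (P, Q) outside the
domain of the logarithm are *saturated*: they get no finite distance,
are flagged, and are excluded from (and counted next to) every summary
mean — clamping them to a ceiling would fabricate data. No gamma rate
heterogeneity is applied; this is the plain K2P estimator.
The uncorrected p-distance is computed alongside as a diagnostic; the
multiple-hit correction guarantees K2P ≥ p wherever both are defined.
Distances are proportions internally and percent in every report.

## Clade inference

Clades within a morphospecies come from one of two sources.

*Threshold clustering* (default): single-linkage agglomerative
clustering cut at a per-locus divergence threshold, computed as the
connected components of the graph whose edges are specimen pairs with
d < t (the two formulations are identical at a fixed cut). Defaults
t(COI) = 0.03 and t(16S) = 0.01 sit inside the empirically observed
separation — intra-clade divergence typically below 1%, COI
inter-clade divergence typically 6% and above, 16S roughly a third of
COI. Merging is strictly below the threshold, so ties at exactly t do
not merge and the result is deterministic and permutation-invariant.
Saturated pairs are treated as exceeding any threshold. Average
linkage is available for robustness checks (scipy hierarchical
clustering, cut just below t to preserve the strict-inequality
convention).

*Imported trees*: when an externally inferred tree with posterior
supports is supplied, clades are the maximal monophyletic groups of
the morphospecies' specimens whose defining node has support ≥ 0.95
(the conventional significance cut for Bayesian posterior
probabilities). Specimens covered by no supported node become
singletons; missing supports are treated as absent, never as zero.

## Gap and ratio tests

For one morphospecies at one locus the package reports per-clade
intra and per-clade-pair inter summaries (mean/min/max, pair counts)
plus pooled means over all intra and all inter pairs — every specimen
pair weighted equally, which is the natural reading of "average
pairwise distance" when clade-pair means are not separately stated.

Two complementary statistics decide delimitation:

- **barcoding gap** (strict): min inter − max intra, present iff > 0;
- **ratio rule**: pooled mean inter ≥ k × pooled mean intra, k = 10
  by default (the 10× rule of thumb used in large polychaete
  barcoding surveys). Zero mean intra with positive inter passes;
  both zero fails.

The verdict for a partitioned morphospecies is:

- one clade → `single_species`;
- gap present **and** ratio passed → `cryptic_species`;
- gap absent but mean inter at least the smallest divergence among
  supplied congeneric reference species → `cryptic_species` with a
  note (low absolute divergence can still be species-level when known
  congeners differ by just as little);
- otherwise → `species_complex` (including the borderline case of a
  positive gap with a sub-k ratio — conservative by design);
- all clades singletons, or no defined cells → `undetermined`.

Two statistics are reported rather than one because borderline cases
should surface, not vanish: a complex with a ratio of 9 and a clean
cryptic split with a ratio of 24 print differently even when both have
positive gaps.

## Four evidence scenarios and MB labels

Per-locus verdicts are reconciled into four classes: S1 — every
sequenced locus cryptic and, when both are present, the clade
partitions coherent on shared specimens; S2 — COI cryptic while 16S
merges the clades (the slower marker under-resolves); S3 — a species
complex or undetermined outcome with no locus establishing cryptic
species; S4 — single species everywhere. Coherence is operationalised
as the absence of a 2×2 all-positive submatrix in the shared-specimen
contingency table (no crossing pairs) — the weakest formal condition
consistent with judging two trees "the same" by eye. Two deliberately
conservative choices: both-loci-cryptic with incompatible partitions
is parked in S3 with a conflict note, and the unobserved mirror of S2
(16S cryptic, COI single) is parked there too. A morphospecies
sequenced at one locus can be S1, S3 or S4, never S2.

Delimited species are named MB# within each morphospecies, numbering
dense from 1 in a deterministic clade order (size descending, then
smallest specimen id); clades of an unresolved complex share one
integer with letters (MB1a, MB1b, …); an unsplit species keeps the
bare "MB". In S1 the labels follow the finer of the two coherent
partitions (ties to COI) so that a clade unsampled at one locus is
still counted. Specimens lacking the discriminating locus are mapped
through the contingency when their block lands entirely in one
labelled clade, and otherwise fall into a bare-"MB" unassigned bucket.

## Richness accounting

Every secondary species carries an origin: `retained` (continues the
primary identification, possibly renamed), `cryptic_split`, or
`morphological_reassignment` (re-examination moved specimens to a
different morphospecies — these enter as input annotations, since no
sequence analysis can produce them). A complex counts once. The
ledger enforces

    total_after = primary + cryptic_additions + reassignment_additions

and raises on labellings that break it (e.g. the same MB integer both
plain and lettered). The headline richness percentage is the
after/before ratio × 100 — 35 species from 15 primaries prints 233 —
a convention stated in the output headers (the percentage *increase*
would be 133). A cryptic lineage that replaces its parent name
one-for-one sets the morphospecies' cryptic flag but adds zero to the
counts; this is the only reading under which a survey's split count,
reassignment count and total all reconcile simultaneously.

## The simulator

`simulate_dataset` plants known structure: each morphospecies gets
1–3 clades built star-wise from a uniform-random root — clade
ancestors at branch length (d_b − d_w)/2 from the root, specimens at
d_w/2 from their ancestor — so expected pairwise K2P is d_w within
and d_b between clades (K2P distances are additive along paths, and
the estimator applied to the endpoint distribution recovers the
branch length exactly in expectation). Evolution is the K2P
continuous-time Markov chain with transition/transversion rate ratio
kappa = 2; each site's end state is drawn from the exact transition
probabilities

    P_ts(t) = 1/4 + 1/4 e^{-4βt} - 1/2 e^{-2(α+β)t},
    P_tv(t) = 1/4 - 1/4 e^{-4βt}  (each transversion),

which is the exact endpoint law of the chain (equivalent to simulating
per-site waiting times, but vectorisable), and makes the analytic
expectation usable directly as a test oracle. Defaults emulate the
survey regime: COI 660 bp / 16S 500 bp, COI evolving 3× faster,
planted COI divergences 0.5% within and 12% between clades, specimen
coverage COI 0.6 / 16S 0.95 with at least one locus per specimen.
Planted divergences beyond 3 substitutions/site are refused as
unreachable (the estimator would be saturated). No indels are
simulated — alignment is out of scope, and gap handling is exercised
with hand-built fixtures instead.

`simulate_scenario_suite` emits one bundle per evidence scenario: S1
(clean separation at both loci), S2 (COI separates; 16S planted at
0.4% between clades, below its 1% threshold, so they merge), S3
(16S-only, 3% within / 5% between — genuinely overlapping
distributions, the unresolved-complex regime), S4 (one clade). Suite
bundles use denser locus coverage (COI 0.8, 16S 1.0) than the ragged
survey-like default so that every planted clade is actually sampled at
the discriminating locus: the bundles test the classifier, not the
sampling design.

What the simulator does *not* emulate: coalescent genealogies within
clades (specimens are conditionally independent given their ancestor),
rate variation across sites, indels/alignment error, contamination,
and reference databases. Passing recovery tests therefore show the
pipeline recovers planted K2P-generated structure, not that the
thresholds are correct for any particular real taxon.

## Numerical and edge-case choices

- Saturation boundary: log argument ≤ 0 → flagged, never clamped.
- Zero comparable sites → `insufficient`, distinct from saturated.
- Clade order, label assignment and report row order are all
  deterministic; end-to-end runs are byte-reproducible given inputs,
  thresholds and seed.
- Richness percent is rounded to the nearest integer for reporting;
  prevalence is reported both as a count and a percentage.
- Distance matrices serialise as square TSV; PHYLIP-style
  lower-triangle input is mirrored on read.

## Problem sizes used in the checks

The bundled accounting fixture is the 15-morphospecies survey table.
Statistical checks use 1,000 random (P, Q) points against a 50-digit
arbitrary-precision oracle (tolerance 1e-12); 12-specimen matrices
against brute-force recomputation; 100 random ≤12-specimen matrices
against a union-find connected-components oracle; 1,000 simulated
pairs of length 10,000 for estimator calibration (3-standard-error
band); and 200 seeded replicates per scenario bundle for recovery
(≥95% required; observed 99–100%).

## Known limitations

- The clustering thresholds are this package's operationalisation of
  clade calls that surveys in practice make from tree topography plus
  expert judgment; they are configurable and should be re-examined per
  taxon.
- The reference-distance fallback needs congeneric distances supplied
  by the user; it is a floor comparison (mean inter ≥ smallest
  reference inter-species distance), not a distributional test.
- Reassignments discovered by secondary morphology cannot be inferred
  from sequences and must be annotated in the input.
- Support-tree import assumes supports are posterior probabilities in
  [0, 1]; bootstrap percentages must be rescaled by the caller.
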