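# barcodegap

Barcoding-gap species delimitation for multi-locus DNA-barcode
surveys — with a built-in K2P sequence simulator so the whole pipeline
is testable without any downloads.

`barcodegap` is aimed at researchers running two-locus (COI + 16S)
barcode surveys of morphologically difficult faunas, where a
"morphospecies" assigned under the microscope may hide several
genetically distinct cryptic species. Given aligned FASTA per locus
and a specimen table, it:

1. computes pairwise **Kimura two-parameter (K2P)** distances
   (`d = -(1/2) ln[(1-2P-Q)√(1-2Q)]`, pairwise deletion of
   gapped/ambiguous sites, saturated pairs flagged rather than
   clamped);
2. partitions each morphospecies into **clades**, by single-linkage
   clustering at a per-locus divergence threshold (COI 3%, 16S 1% by
   default) or from an imported Newick tree with posterior supports
   (clades = maximal monophyletic groups with support ≥ 0.95);
3. tests each partition for a **barcoding gap** (min inter-clade minus
   max intra-clade distance) and against the **10× rule** (mean inter ≥
   10 × mean intra), yielding a verdict: single species, cryptic
   species, species complex, or undetermined;
4. reconciles the per-locus verdicts into one of **four evidence
   scenarios** (S1 coherent cryptic at all sequenced loci; S2 cryptic
   in COI but merged in 16S; S3 unresolved complex; S4 no cryptic
   signal) and assigns **MB species labels** (MB1, MB2, … for cryptic
   species; MB1a, MB1b, … for clades of an unresolved complex);
5. tallies the **species ledger**: primary morphospecies, cryptic
   additions, morphological reassignments, total secondary species,
   and the headline richness ratio (after/before × 100).

See `docs/methods.md` for the model, the decision rules and their
rationale, and what the simulator does and does not emulate.

## Worked example

Simulate a small survey with planted cryptic structure and delimit it:

```
$ barcodegap simulate --out demo --seed 3 --n-morphospecies 2
wrote 15 specimens to demo

$ barcodegap delimit --coi demo/COI.fasta --16s demo/16S.fasta \
      --meta demo/metadata.csv --out demo-results
thresholds: {"clustering": {"COI": 0.03, "16S": 0.01}, "linkage": "single", "min_support": 0.95, "ratio_k": 10.0}
{
  "primary": 2,
  "cryptic_additions": 1,
  "reassignment_additions": 0,
  "total": 3,
  "richness_percent": 150,
  "cryptic_morphospecies": 1,
  "cryptic_prevalence": 0.5
}
```

The two simulated morphospecies were planted with one and two clades;
the pipeline finds the split (one cryptic addition), so 2 primary
morphospecies become 3 species — a richness ratio of 150%.
`demo-results/` also contains the per-locus distance matrices (percent),
the clade partitions, a per-species table with MB labels and scenarios,
and a per-morphospecies table of mean intra-/inter-clade K2P.

The package ships a sequence-free species table for a real survey of
15 deep-sea Antarctic polychaete morphospecies. Running only the
accounting on it:

```
$ python -c "from importlib import resources; print(resources.files('barcodegap.data')/'antarctic_polychaetes.tsv')"
$ barcodegap delimit --ledger-only <that path> --out ledger-out
{
  "primary": 15,
  "cryptic_additions": 10,
  "reassignment_additions": 10,
  "total": 35,
  "richness_percent": 233,
  "cryptic_morphospecies": 8,
  "cryptic_prevalence": 0.5333
}
```

15 morphospecies became 35 species: 10 extra cryptic species (found in
8 of the 15 morphospecies) plus 10 morphospecies uncovered by
post-sequencing morphological re-examination — a 233% richness ratio.

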