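# cleftvar

Rare-variant prioritization and locus association toolkit for whole-exome
studies of non-syndromic cleft lip with or without cleft palate (ns-CL/P),
and similar rare-disease cohorts that combine in-silico variant annotation,
trio segregation, a common-variant companion scan and gene-set enrichment.

It is written for analysts who already have annotated variant tables
(dbNSFP-style predictor columns), trio genotypes from targeted
resequencing, per-gene constraint/dominance evidence, and — optionally —
case-control genotype counts and GMT gene sets. The package supplies the
decision logic and statistics between those inputs and a final candidate
list:

- **Prioritization cascade** — consequence screen; rarity filter
  (gnomAD NFE MAF < 10⁻⁴, missing frequency = rare, ClinVar rescue for
  trait-specific likely-pathogenic variants); per-class rules: missense
  needs CADD ≥ 20 *and* a "at least half of applied tools" consensus over
  22 dbNSFP predictors (REVEL ≥ 0.644 counts as pathogenic), splice-region
  needs ADA ≥ 0.9, stop/frameshift qualify by class with MutPred-LOF ≥
  0.50 as a soft (optionally strict) support flag; gene tiers from prior
  orofacial-cleft evidence or pLI ≥ 0.95 + dominant DOMINO class.
- **Segregation** — de novo (verified parentage, both parents wild type)
  vs inheritance from an affected or unaffected parent; cis grouping;
  sibling-shared variants.
- **Locus scan** — per-SNV Cochran-Armitage trend test
  (χ² = T²/Var(T), T = Σ wᵢ(nᵢS − mᵢR)) and minor-allele allelic odds
  ratios over gene ± 100 kb windows, with gene-level (α/G) and SNV-level
  (α/M) Bonferroni thresholds.
- **ORA** — hypergeometric upper-tail over-representation of a query gene
  list against GMT gene sets, Bonferroni-adjusted.
- **Fixtures** — the source study's published tables ship as plain TSV
  (variant annotation grid, trio genotypes, locus-scan summaries, cohort
  counts), so the published counts are reproducible offline.
- **Synthetic cohorts** — seeded generators (annotation grids, trios,
  Hardy-Weinberg case-control counts with a planted odds ratio, gene sets)
  with the study's default conditions, used throughout the test suite.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Materialize the packaged study tables and run the cascade and the
segregation classifier:

```sh
cleftvar fixtures --name variants -o fx
cleftvar fixtures --name evidence -o fx
cleftvar fixtures --name trios    -o fx

cleftvar classify --variants fx/variants.tsv --evidence fx/evidence.tsv -o classified.tsv
# passed: 31 variants in 30 genes -> classified.tsv

cleftvar classify --variants fx/variants.tsv --strict-lof -o strict.tsv
# passed: 30 variants in 29 genes -> strict.tsv

cleftvar segregate --trios fx/trios.tsv -o seg.tsv
# INFO cleftvar: mode de_novo: 3
# INFO cleftvar: mode inherited_affected: 3
# INFO cleftvar: mode inherited_unaffected: 25
# INFO cleftvar: sibling-shared LRP5:c.3638-1G>A: CLP_11,CLP_12
# classified 32 trios -> seg.tsv
```

The default run reproduces the published final set: 31 likely-pathogenic
variants across 30 genes. Strict LoF mode additionally requires
MutPred-LOF ≥ 0.50 for stop/frameshift variants and drops exactly one
stop-gain variant (score 0.45), leaving 30. The trio table classifies into
3 de novo, 3 inherited from an affected parent and 25 from healthy parents
(the splice variant shared by a sibling pair is counted once), and the two
same-gene variants transmitted by one father are grouped as a cis pair.
The output TSV carries one row per variant:

```
variant_id      gene    consequence  status  exclusion_stage  gene_tier
AGO1:c.1823C>T  AGO1    missense     passed                   constrained_dominant
ARID1A:c.6428G>A ARID1A missense     passed                   constrained_dominant
```

The same operations are available as library functions
(`cleftvar.run_cascade`, `cleftvar.classify_trios`, `cleftvar.scan`,
`cleftvar.run_ora`, `cleftvar.fixtures.final_variant_set`, ...).

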