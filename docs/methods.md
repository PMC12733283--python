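# Methods

`cleftvar` packages the statistical and rule-based machinery of a
whole-exome rare-variant study of non-syndromic cleft lip with or without
cleft palate (ns-CL/P): candidate-variant prioritization from in-silico
annotations, trio segregation, a companion common-variant locus scan, and
gene-set over-representation analysis. This note describes each model, its
assumptions, the parameters that matter, and what the synthetic-data tests
do and do not establish.

## Prioritization cascade

A variant survives the cascade when it passes, in order:

1. **Consequence screen.** Only exonic and splice-region consequences are
   considered; synonymous substitutions and the catch-all `other` class are
   removed first.
2. **Rarity.** gnomAD European non-Finnish (NFE) allele frequency below
   `maf_threshold` (default `1e-4`). Two deliberate asymmetries:
   a *missing* frequency is treated as rare, not as zero — novel variants
   are the object of the study, and representing "not reported" as 0 would
   hide the distinction; and a variant previously classified likely
   pathogenic for the trait in ClinVar is *rescued* regardless of
   frequency (`clinvar_rescue`, default on). The rescue path exists because
   the trait-specific prior classification is treated as stronger evidence
   than a population-frequency prior; it is switchable for strict
   frequency-only filtering.
3. **Per-class prediction rules.**
   - *Missense*: CADD (PHRED) >= `cadd_min` (default 20, roughly the top 1%
     most deleterious substitutions) **and** a consensus majority of the 22
     categorical predictors (below).
   - *Splice-region*: dbscSNV-style ADA score >= `ada_min` (default 0.9).
   - *Stop-gain / stop-loss / frameshift / in-frame indel*: qualify by
     consequence class as likely gene-disrupting. MutPred-LOF (threshold
     0.50) is carried as a **soft** support annotation rather than a hard
     filter, because a nonsense variant with a middling score is still
     gene-disrupting by mechanism; `lof_strict=True` turns the threshold
     into a hard filter for sensitivity analyses.

### Predictor consensus

Each of the 22 dbNSFP predictors (SIFT through BayesDel_noAF) emits a
categorical label, except REVEL, which is numeric in [0, 1]. Labels are
binarized: {D, H, M, P, PS, PM, PP, LP} count as pathogenic; {A, B, BM, BP,
L, N, T, UC} as not pathogenic — ambiguous/uncertain labels deliberately
vote *against*, making the consensus conservative. REVEL binarizes at
0.644, the lower bound of its "pathogenic supporting" band; both the
"neutral" (0.291-0.643) and "benign supporting" (<=0.290) bands map to not
pathogenic since the vote is binary. A variant reaches *majority* when
`2·k >= n` over the `n` predictors that produced a call (`n >= 1`): ties
pass, matching the "at least half" reading; the inclusive comparison is
required for one published variant that collects 9 pathogenic calls from 17
applied tools. CADD, DANN and ADA never enter the vote denominator — they
are thresholds or annotations, not voters.

### Gene tiers

Gene-level evidence ranks surviving variants without excluding any
(`prior_ofc_evidence` > `constrained_dominant` > `other`). The first tier
is any prior orofacial-cleft link (human syndromic or non-syndromic
association, or a cleft phenotype in knockout mice); the second is
constraint plus dominance: pLI >= 0.95 and a DOMINO class of likely or very
likely dominant. The printed DOMINO *class* drives the logic, not the
numeric probability: the packaged tables print both, and the classes are
authoritative (the class/probability band mapping is asserted to be
monotone in the fixture tests, not assumed).

## Trio segregation

For a carrier proband: *de novo* requires both parents wild type **and**
verified parentage (unverified parentage with wild-type parents is
`uninformative`, never de novo); exactly one carrier parent gives
*inherited from affected parent* or *inherited from unaffected parent*
according to that parent's phenotype for the studied trait — extended
family history does not make a transmitting parent "affected"; missing
parental genotypes or two carrier parents are `uninformative`. A wild-type
or missing proband genotype is an input error, not a class.

Variants sharing proband, gene, inheritance mode and transmitting parent
are grouped as putative *cis* pairs (no phasing data is consumed; identical
transmission in one person is the available evidence). Variants carried by
two or more probands of one family are flagged *sibling-shared*; in final
tallies such a variant counts once, attributed to the index proband, which
is why the packaged trio table has 32 carrier rows but tallies to 31
variants (3 de novo + 3 from an affected parent + 25 from healthy parents).

## Common-variant locus scan

Windows are the gene body ± `flank_bp` (default 100 kb), closed, 1-based.
Within a window, SNVs with pooled (cases + controls) minor-allele frequency
>= `maf_min` (default 0.05) are tested with the Cochran-Armitage trend
test, the 1-df chi-square score test for a linear trend in case proportion
across genotype copy classes:

    T      = Σᵢ wᵢ (nᵢ·S − mᵢ·R)
    Var(T) = (R·S/N) · [N·Σᵢ wᵢ²·cᵢ − (Σᵢ wᵢ·cᵢ)²]
    χ²     = T²/Var(T),  p = P(χ²₁ >= χ²)

with case counts nᵢ, control counts mᵢ, column totals cᵢ, R cases, S
controls, N = R+S, and weights w = (0, 1, 2) (the statistic is invariant to
affine re-weighting). With two genotype classes this reduces exactly to the
Pearson chi-square of the collapsed 2×2 table; the test suite verifies the
statistic against an independently coded subject-level form (χ² = N·r²,
with r the Pearson correlation of genotype score and case status), against
R's `prop.trend.test` values, and against a label-permutation null. A
monomorphic table returns χ² = 0, p = 1.

Effect size is the allelic odds ratio of the collapsed allele counts,
oriented to the pooled minor allele; with any zero cell the
Haldane-Anscombe correction (+0.5 to all four cells) keeps it finite.
Counts are oriented to the minor allele before testing (the trend test is
orientation-invariant; the OR is reported for the minor allele). Two
Bonferroni thresholds are emitted: alpha divided by the number of gene
loci, and alpha divided by the number of distinct SNVs tested (an SNV in
overlapping windows counts once). Per-gene best signals take the minimal
trend p, ties broken by position then identifier, so outputs are
deterministic.

The published per-SNV p-values and odds ratios of the source scan are
carried as fixture annotations only: the underlying genotypes are not
distributed, so those numbers are not recomputable. Their statistical
machinery is validated in simulation space instead (see below).

### Comparing the asymptotic p to a permutation null

Exact label-permutation p-values of a discrete 2×3 table are systematically
conservative relative to the chi-square approximation (the same
discreteness effect as Fisher's exact test versus Pearson's chi-square), so
the package's agreement checks compare the asymptotic p to the permutation
**mid-p** (half weight on the observed atom), the standard convention when
a continuous approximation is compared with a discrete null. At 60 subjects
the two agree to about 0.01 absolute in the p ∈ [0.01, 0.5] regime; the
test tolerance is 0.015 plus three Monte Carlo standard errors of the
100 000-replicate permutation estimate.

## Over-representation analysis

Standard hypergeometric upper tail: with N background genes, K set members,
n query genes in the background and k overlapping, p = P(X >= k). The tail
is computed by `scipy.stats.hypergeom` (log-space internally) and verified
against exact rational enumeration for all N <= 60. Adjustment is
Bonferroni over the number of sets with at least one background member
(matching the source analysis); Benjamini-Hochberg FDR is available behind
a flag but off by default. Symbols match case-insensitively; query genes
outside the background are dropped with a warning. The source study's GO
term lists and p-values depend on a live annotation release and a web
backend, so they are not reproduction targets; the module reproduces the
statistic, not the database.

## Synthetic cohorts

The generators produce inputs with the statistical structure the analysis
assumes, so every stage is testable without external data. Defaults are
the emulated study conditions: 58 probands with 3-8 candidate variants
each; planted likely-pathogenic fraction 0.12 (31 of 263 confirmed
candidates); de novo rate 0.1 (3 of 31); carrier-parent penetrance 0.1
(3 of 28 inherited variants came from an affected parent); predictor
sensitivity and specificity 0.9 with 10% per-tool missingness;
class-conditional CADD normal with means (10, 28) and spread 5, truncated
at 0; pathogenic variants' population frequency log-uniform on
[1e-7, 1e-4] versus [1e-7, 1e-2] for benign (rare-biased); case-control
arm of 269 cases / 569 controls with control minor-allele frequency 0.18
and planted allelic OR 1.62 (the strongest reported locus signal). The
planted case allele frequency uses the odds transform
p₁ = OR·p₀ / (1 − p₀ + OR·p₀), and genotypes are Hardy-Weinberg draws
within each group.

Simplifications, and what passing tests therefore do **not** show about
real data: predictor errors are independent across tools by default (real
meta-predictors are strongly correlated; a shared-latent-error probability
`predictor_correlation` is available, default 0); the latent pathogenicity
label is independent of consequence class; trios contain no genotyping
error, no missing parents and no misattributed parentage; case-control
genotypes have no linkage disequilibrium, population stratification or
genotyping batch structure. Recovery and calibration results on these
cohorts demonstrate correctness of the implemented rules and statistics
under their own assumptions, not field performance on real exomes or
array data.

## Numerical and design choices

- Thresholds are inclusive (CADD >= 20, ADA >= 0.9, MutPred-LOF >= 0.50,
  REVEL >= 0.644, pLI >= 0.95, "at least half") — each boundary is pinned
  by a test.
- The rarity comparison is strict (MAF < threshold).
- p-values are floored at the smallest positive double; the hypergeometric
  tail is clipped into (0, 1].
- I/O coordinates are 1-based fully closed (VCF convention); window
  arithmetic is performed directly on closed intervals.
- All randomness flows through `numpy.random.Generator` objects created
  per call from an explicit seed; no global state.
- Problem sizes in the test suite (1000 random tables, 10⁴ null
  replicates, 10⁵ permutations, 1000-variant synthetic grids) were chosen
  to give tight Monte Carlo error for each property while keeping the
  default suite fast.

## Known limitations

- Compound heterozygotes, X-linked inheritance and multi-allelic site
  decomposition beyond simple splitting are out of scope.
- The cascade reproduces the published final-set counts from the packaged
  annotation grid; the upstream funnel from raw exomes (e.g. the 263
  confirmation candidates) is not reconstructible without the primary
  sequence data and is reported only as stage counts on whatever input is
  provided.
- The packaged tables transcribe the printed study tables; genomic
  coordinates for the rare variants are not printed there, so fixture
  variant records carry gene + HGVS identity without chrom/pos.
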