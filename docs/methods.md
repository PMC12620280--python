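# Methods

This note documents the models, parameter choices and numerical decisions
behind lincscout, and what the synthetic validation does and does not show
about real data.

## Discovery cascade

A transcript model is a sorted, disjoint exon chain on one chromosome and
strand in 0-based half-open coordinates (GTF is converted on read/write,
BED is native; a single internal convention removes off-by-one drift).
Eight boolean criteria are evaluated independently for every assembled
transcript — no short-circuiting — so each rejection is attributable to a
specific criterion:

| flag | definition | default |
|---|---|---|
| `length_gt_200` | spliced length strictly greater than the lncRNA bound | 200 bp |
| `intergenic` | no exon overlaps any annotated gene | gene-span mode, strand-agnostic |
| `mean_rpkm_ge_0.5` | mean RPKM over **all** samples, inclusive boundary | 0.5 |
| `dnase_support`, `h3k4me3_support` | ≥1 peak within ±window of the TSS | 1 kb |
| `multi_exon` | ≥2 exons | — |
| `exon_size_ok` | longest exon below the retained-intron bound | 10 kb |
| `de_significant` | BH *q* < FDR and linear fold change > threshold | 0.05, 1.5 |

Design choices where the procedure was genuinely open:

- *Intergenicity* is tested against full gene spans (introns count as
  genic) on either strand, because a lincRNA definition should exclude any
  overlap with an annotated locus; `exonic` mode and stranded matching are
  available for sensitivity analyses. Transcripts on chromosomes absent
  from the annotation are classified intergenic with a logged warning.
- *"Abnormally long exon"* has no canonical bound; 10 kb is generous enough
  to keep real multi-kb terminal exons while rejecting retained introns.
- *TSS support window* of ±1 kb reflects typical promoter-mark peak width.
- *Differential expression* is a two-sided Welch *t*-test on log₂(CPM+1)
  with Benjamini–Hochberg correction — a deliberate, documented engine
  choice; the thresholds (FDR 0.05, FC 1.5) are the interface, not the
  engine. The fold change is computed on the CPM scale with a 1-CPM
  pseudocount for stability at zero counts; log₂FC > 0 means higher in
  group A, stated in every report header. Features with zero variance in
  both groups get *p* = 1 when the means agree.

## Isoform usage

Usage of a declared alternative-exon set (e.g. three start exons) is
quantified per sample from exon-level counts. Expression is
length-normalized log₂(CPM+1) (the reporting/statistics scale); the usage
*share* is computed on the linear length-normalized CPM scale so shares sum
to one per sample. The optional filter keeping only samples with CPM > 0 in
every exon of the set is on by default and the number of dropped samples is
reported; removing it can only add samples, never change retained shares.
Two-exon sets are compared by paired *t*; larger sets by one-way
repeated-measures ANOVA with paired-*t* post-hocs, Holm-adjusted (the
multiplicity method was an open choice; Holm is assumption-light).

## Cohort statistics

- Expressor bins partition [0,∞) of log₂(CPM+1): exactly 0, (0, 0.5],
  (0.5, 2], (2, ∞) — left-open/right-closed, with exact zeros their own
  class; the first two classes are non-expressors.
- Subgroup association uses tie-corrected Kruskal–Wallis; Dunn's pairwise
  z-tests on mean ranks (with the Σ(t³−t)/(12(N−1)) tie term) are
  implemented directly and Holm-adjusted. An all-tied input returns
  H = 0, p = 1 rather than an error.
- The median-split helper sends samples exactly at the median to the
  "high" group (deterministic tie rule); the split is identical for CPM
  and log₂(CPM+1) because the transform is monotone.
- Survival records carry an optional transplant time; when it precedes the
  event the record is censored at transplantation before any estimator
  runs. Kaplan–Meier curves, the log-rank test and the Cox model come from
  lifelines (Efron tie handling); with zero events the log-rank statistic
  is reported as missing rather than raised. Wald CIs and p-values are
  reported per covariate; constant covariates and under-determined fits
  (events < covariates) are rejected up front.
- ΔΔCT: RQ = 2^−((Ct_t − Ct_c) − (Ct_t,ref − Ct_c,ref)). Fraction
  distributions divide signal by a positive spike per fraction and
  renormalize to percent, which sums to 100 by construction.

## ChIRP post-processing

Replicate consensus keeps a peak of replicate 1 iff it overlaps a
replicate-2 peak by ≥ min_overlap (default 1 bp); coordinates are merged by
union (default, conservative boundaries) or pairwise intersection, and
outputs are coalesced, making the operation idempotent.

Each peak receives exactly one category by precedence promoter > 5′UTR >
3′UTR > exon > intron > downstream > distal intergenic, with 3 kb promoter
and downstream windows; the "exon" category means coding-exon overlap
beyond any UTR-covered bases. Precedence order was an open choice and is
configurable. The nearest gene (by signed TSS distance) is recorded for
every peak; peak-to-gene mapping takes genes with ≥1 non-distal peak
(distal peaks can be included by nearest gene on request).

Chromatin-state enrichment assigns peaks to states by midpoint (avoids
fractional-overlap ambiguity), validates that the state segments tile each
chromosome exactly, and estimates expectations by uniformly re-placing
equal-length peaks (seeded; two-sided empirical p with add-one correction).
With zero shuffles the analytic expectation (coverage fraction × peak
count) is used.

Gene-set overlap uses the upper-tail hypergeometric probability
P[X ≥ k]; the universe size must be passed explicitly and is echoed in
every result because p depends on it strongly — no default universe is
guessed.

## Drug screen

Inhibition curves are fitted with the four-parameter logistic
y = bottom + (top − bottom)/(1 + (c/IC₅₀)^hill) (hill < 0 for rising
inhibition data); flat series are flagged degenerate and represented by
their constant level rather than a sham fit. DSS integrates
max(0, min(y,100) − 10) over the tested log₁₀ concentration range by
adaptive quadrature, normalized to [0,100] (0 = never above the activity
threshold, 100 = complete inhibition throughout). The exact DSS variant in
the platform literature is proprietary; this normalized area-above-threshold
preserves its ordering semantics, and the variant is stated in the report.
Replicates are averaged at the response level before fitting (per-replicate
fits with DSS averaging are available). sDSS = DSS(group A) − DSS(group B);
the sign convention (knockout minus wild-type) is printed in output
metadata since either convention is defensible.

## Synthetic-data generator

The generator emulates an AML-versus-normal-bone-marrow discovery study on
a 3 × 2 Mb genome laid out in 12 kb slots: even slots host 200 reference
genes (3–5 exons, 100 bp terminal UTRs), odd slots host the assembled
novel transcripts, so intergenicity holds by construction and the "genic"
decoy class violates it deliberately. Ten candidates and five decoys per
class are planted; each decoy class isolates exactly one criterion
(too-short, genic, low-expression, no-marks, single-exon, monster-exon,
not-DE), which makes filter attribution exactly testable.

Counts are negative-binomial with var = μ + μ²·φ. Defaults: 20 AML-like
vs 10 NBM-like samples; gene base means 200–2000 counts (so library sizes
are dominated by the annotated transcriptome, as in real quantification);
novel-transcript base means 30–100 counts (lncRNA-typical low expression);
dispersion φ = 0.02 (cell-line-grade biological noise); planted |log₂FC|
uniform in [2, 4] with random sign — a cohort has both over- and
under-expressed transcripts, and one-sided planting would bias CPM
normalization of every null feature through library-size composition.
Exon-level counts are a length-proportional multinomial split of the
transcript count, so exon sums equal transcript counts exactly. A separate
generator plants a molar start-exon mixture for isoform-usage validation.

Support tracks place a peak at every TSS except the no-marks decoys
(background peaks avoid their windows). ChIRP consensus sites sit in
promoters/first introns of 40 randomly chosen genes; each replicate jitters
them by ≤50 bp and adds private noise peaks in disjoint unannotated blocks,
so consensus recovery is exact by construction. Chromatin states tile each
chromosome in 50 kb blocks over five states.

The clinical cohort (n = 300) mixes expression classes and plants high
expression in APL-like and NPM1/IDH2-R140 co-mutant patients; survival is
exponential with hazard λ₀·exp(β·x) for the high-expressor indicator,
β = ln 0.63, uniform administrative censoring on [300, 2500] days and a
25% transplant-censoring fraction with transplant times on [50, 600] days.
Drug plates are 8-point 1:3 dilutions from 15 µM, three replicates per
group, Gaussian response noise (σ = 1% inhibition); the differential
drug's KO IC₅₀ is solved by bisection so the noiseless DSS difference
equals the planted 1.6, and all other drugs share parameters across groups.

All outputs are pure functions of (config, seed); one root seed streams
named per-component sub-seeds so stages can be regenerated independently.

### What passing tests show — and what they do not

The generator plants clean, separable truth: decoys violate one criterion
with margin, noise levels leave ≥5σ between null fold-change estimates and
the 1.5-fold gate, and ChIRP noise peaks never straddle replicates. Passing
therefore demonstrates that the machinery is correct and calibrated — not
that real studies achieve precision/recall 1. Real data add unmodeled
effects this generator deliberately omits: patient-level overdispersion and
batch structure, annotation incompleteness, fragmentary transcript
assembly, GC/length biases, peak-caller artifacts, and composition bias
beyond what random-sign planting cancels. Numbers derived from patient
cohorts (e.g. a hazard ratio of 0.63, a selective DSS of 1.6) are used as
planted parameters to check estimator recovery, not re-derived from raw
data.

## Problem sizes and numerics

Default scale (3 chromosomes × 2 Mb, 200 genes, 45 assembled transcripts,
30 RNA-seq samples, 300 patients, 5 drugs) runs in seconds; calibration
checks use 2000 features × 40 samples, and survival-coverage checks use
600 replicates at n = 2000 — sizes chosen so the Monte-Carlo error on each
estimated proportion is small relative to the margin being tested.
Numerical details: BH q-values via statsmodels; Welch *t* degenerate inputs
handled explicitly (see above); 4PL fits are bounded least squares with
data-driven initialization (bottom/top from the response range, IC₅₀ from
the geometric-mean concentration) and 20 000 evaluation cap; quadrature via
scipy `quad`; hypergeometric tails via `hypergeom.sf(k−1, …)`; all
randomness flows through `numpy.random.Generator` seeded from one root.

## Known limitations

- No FASTA/sequence handling, liftover, coding-potential scoring, peak
  calling or transcript assembly — inputs are annotations, counts and
  called peaks.
- The DE stage is a location test on transformed CPM, not a count-model
  fit; with few samples or strong composition effects a dedicated NB model
  with robust normalization would behave differently.
- Peak annotation is O(peaks × transcripts) per chromosome — fine at the
  scales here, but large annotations would warrant an interval-tree pass.
- The hypergeometric overlap test treats gene sets as exchangeable draws
  from the universe; expression-dependent detectability is not modeled.
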