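# Methods

## Data model

A cohort is four aligned tables over a shared sample universe (the union
of sample identifiers across tables): gene × sample GISTIC copy-number
calls in {−2, −1, 0, +1, +2}, gene × sample expression z-scores, a
per-mutation record table, and a per-sample clinical table. Samples may
be present in some tables and absent from others; every analysis stage
applies its own complete-case rule rather than enforcing a global
intersection, because the annotation layers of public tumor cohorts have
very different coverage (in the TCGA breast cohort the package mirrors:
958 tumors with copy-number data, 492 with subtype, 770 with survival).
Files are tab-delimited UTF-8 with `NA` for missing values; mutation
tables are also accepted in minimal MAF form (`Hugo_Symbol`,
`Tumor_Sample_Barcode`, `Variant_Classification`, `HGVSp_Short`), with
variant classifications normalized case-insensitively onto a seven-type
vocabulary (missense, nonsense, frameshift del/ins, splice, inframe
ins/del); silent and non-coding records are dropped at parse time. Gene
symbols are matched verbatim — the shipped alias table is reference
material, not an automatic resolver, because silent alias remapping is a
classic source of irreproducible gene lists.

## Alteration landscape

Per-gene frequencies are `100 · count(call == category) / n_evaluable`,
where the denominator is the per-gene count of non-missing calls (with a
complete matrix this equals the cohort size). Mutation frequency counts
*samples* with ≥1 record, whereas the mutation spectrum counts *records*;
both are exposed and deliberately never conflated — for KMT2C the same
cohort yields 67 mutated samples but 80 mutation records. Subtype-
stratified frequencies cover the four major subtypes; normal-like is
excluded from stratification because eight samples cannot support
frequency estimates. Threshold selection uses strict inequalities
(amplification >5%, homozygous deletion >2%, mutation >2%), so a gene at
exactly 5.00% is not selected. Unrounded values are compared; rounding
to two decimals happens only when tables are written.

Co-amplification over a locus set counts a sample as amplified at a
locus iff its call is +2, and reports: samples amplified at ≥1 locus, at
all loci, at exactly one locus (per locus), and all pairwise counts.

## Dosage correlation

The copy-number variable is the discrete GISTIC call, so ties dominate;
Spearman therefore uses average ranks and Kendall uses tau-b with tie
correction. P-values: Spearman and Pearson via the t approximation with
n−2 degrees of freedom, Kendall via the tie-corrected normal
approximation. At the cohort sizes involved (~958) the t approximation
is accurate to well past the decision thresholds; the test suite pins
all three coefficients to brute-force oracles (rank sorting, pair
enumeration) on small samples. The published correlation table prints
coefficients without p-values; where a p-value is needed for screening,
it is recomputed from r at n = 958 via the same t approximation.

## Basal vs non-basal expression

Two-sided two-sample t-test of expression between basal-like and all
other subtyped samples. Welch's unequal-variance form is the default:
the groups are strongly unbalanced (≈88 vs 404) and nothing guarantees
equal variances; the pooled Student form is available via an argument
for sensitivity. Normal-like samples stay in the non-basal group by
default (they are subtyped samples that are not basal-like); a flag
drops them. The sign convention is basal minus non-basal, so positive t
means higher expression in basal-like tumors.

## Survival

Copy-number grouping pools {+1, +2} as amp/gain and {−1, −2} as deletion
against diploid; expression grouping is a median split with ties going
to the low group (deterministic; the split is exactly equal only for
distinct values — 770 distinct z-scores split 385/385). Kaplan–Meier,
log-rank and Cox fits are computed with lifelines. The omnibus log-rank
runs over all groups (df = groups − 1); pairwise tests against the
reference group (diploid, or low expression) are reported alongside, and
downstream scoring uses the *minimum* pairwise p, because either
direction of copy-number change may carry the association (for SETDB2
both deletion and amp/gain associate with shorter survival). Hazard
ratios are `exp(beta)` from a Cox fit with 95% CI `exp(beta ± 1.96·se)`.
The multivariate model adjusts the gene exposure (copy-number group
indicators with diploid reference, or the high-expression indicator) for
age, ER/PR/HER2 status (pos = 1/neg = 0), ordinal tumor size, node and
metastasis codes, and a basal indicator, over complete cases; constant
columns are dropped with a warning and a rank-deficient design raises an
error naming a collinear pair. Tied event times use Efron's method,
lifelines' only tie convention; on tie-free data this coincides with
Breslow, which the tests verify against an independent Newton–Raphson
partial-likelihood fit. Follow-up times must be positive; non-positive
times are dropped with a warning.

## Mutation spectrum

Protein positions are the first integer run of the HGVS-short protein
change (`D3264N` → 3264, `Q1218*` → 1218); insertions and deletions use
their leftmost coordinate, matching single-position lollipop plotting.
Domain annotations are supplied as Pfam-style TSVs with 1-based
inclusive bounds (the analysis driver ships synthetic demonstration
coordinates, clearly labelled, since curated bounds are an external
input). A position overlapping several domains counts in each;
positions in no domain go to an inter-domain bin; records without a
parseable position are counted separately, so positioned + unparseable
always equals the record total.

## Integrative score

Each of the five criteria contributes one point (see README table); all
cut-offs are strict and configurable, so relaxing any threshold can only
raise scores (a monotonicity the tests check). Scoring runs over the
whole input gene universe — restricting the report to the
threshold-selected genes is a presentation choice, since genes outside
that set can still satisfy other criteria (SETD2, for example, passes
both the dosage-correlation and CNA–survival screens). A gene missing a
stage (e.g. no RNA-seq data, as for KMT2D) scores False on the affected
criteria with a warning. Ranking is by score descending with
alphabetical tie-breaks. The expression criterion counts either
direction of change: SMYD3 earns its expression point by significantly
*lower* expression in basal-like tumors.

The packaged survival fixture stores the reported expression-split
p-values; for the copy-number analysis only the significant gene list is
reported in the source, so those rows carry a placeholder p = 0.049
(marked as such in the file) that is strictly below the 0.05 reporting
level and only ever enters threshold comparisons at 0.05/0.1.

## Synthetic cohorts

The generator emulates the structure the stages consume, not the
biology: per-gene multinomial calls (optionally subtype-conditional);
expression `z = beta·call + delta_basal·1[basal] + N(0, sigma)`,
standardized per gene, giving a rank correlation tunable through
`beta/sigma` (≈0.7 population Spearman at beta/sigma ≈ 1.1 under a
typical call distribution); mutation hit counts Poisson with rate
`−log(1−p)` so the mutated-sample fraction is exactly `p` in
expectation, with types drawn from a spectrum and positions uniform on
the protein; survival exponential with per-group log-hazard shifts and
independent Uniform(0, max follow-up) censoring. Subtype labels and
survival-annotation membership use exact largest-remainder allocation of
`n·weight` followed by a seeded shuffle, so cohort-level counts
(492/958 subtyped, 770/958 with follow-up) are exact while everything
per-sample is stochastic. Randomness derives from per-table, per-gene
substreams keyed by stable string tags, so identical spec + seed gives
byte-identical files and adding a gene never perturbs existing columns.

The defaults of `paper_like_spec` are the published cohort's marginal
frequencies (subtype breakdown 8/220/121/55/88 of 492; per-gene category
and mutation frequencies from the packaged table, renormalized over the
five categories to absorb the rounding of printed percentages; survival
coverage 770/958). Where the source states no value the defaults are
one-time choices at realistic scale: baseline hazard 0.005/month
(median ≈ 139 months, consistent with the high long-term survival of a
mostly early-stage breast-cancer cohort), 240 months maximum follow-up,
uniform dosage coupling beta = sigma = 1. What passing on synthetic data
shows is that the *estimators and decision rules* behave correctly at
the stated sizes; the generator has no linkage along chromosomes, no
subtype-specific copy-number structure and no real survival effects, so
it cannot validate biological conclusions.

## Problem sizes and numerical choices

Statistical property checks run at sizes chosen to make their tolerances
meaningful on one CPU: frequency recovery at n = 100 000 (3 binomial SE),
log-rank type-I error over 2000 null replicates at n = 60 (band
[0.04, 0.06]), Cox HR = 2 recovery at n = 2000 (±10%), CI coverage over
1000 replicates at n = 150 via the validated Newton–Raphson oracle
(95% ± 2%), and t-test calibration over 1000 vectorized null genes at
88 vs 404. Brute-force oracle comparisons use n ≤ 10–15 with tolerances
of 1e−9 to 1e−12 (floating-point noise only).

## Known limitations

- Copy-number input is categorical GISTIC calls; linear copy-ratio data
  are out of scope, as is recomputing segmentation or GISTIC itself.
- No multiple-testing correction is applied in the correlation screen or
  the scoring criteria (matching the published procedure); an FDR
  variant would be a straightforward extension but is not the default.
- No time-varying covariates, competing risks or proportional-hazards
  diagnostics beyond convergence checks.
- Breslow tie handling is not offered (lifelines implements Efron only);
  the Efron/Breslow agreement is verified on tie-free data instead.
- The scorer consumes stage summaries; it is agnostic to whether they
  came from a real export, the simulator, or the packaged fixtures.
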