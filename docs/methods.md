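# Methods

This note documents the statistical models, parameter defaults, numerical
choices and known limitations of `dnmburden`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Data model and conventions

A cohort is a set of independent trios, each with paternal age, maternal
age (years) and gestational age (weeks); a newborn is preterm iff
gestational age < 37.0 weeks (strict). Gestational ages outside 20–45
weeks are rejected at read time; a day-valued column is converted by ÷7.
Mutation positions are 1-based (VCF convention); all interval files are
0-based half-open (BED convention); conversions happen only at I/O
boundaries. Chromosome labels are matched after stripping an optional
`chr` prefix; the autosome set is {1..22} and burden counts autosomal
mutations only. Unknown consequence labels degrade to `other` (with a
logged warning) rather than erroring, so partially annotated inputs remain
usable. Gene symbols are matched case-insensitively after whitespace
stripping; no alias resolution is attempted.

## Burden inference

**Wilcoxon rank-sum.** Midranks for ties; the reported statistic is
U for the first group (pairs with x > y, ties ½). The normal approximation
uses the tie-corrected variance
`m·n/12 · ((N+1) − Σ(t³−t)/(N(N−1)))`; the continuity correction is **off
by default** (available via a flag). When both groups have ≤ 12
observations the p-value comes from full enumeration of all C(N, m)
midrank assignments (two-sided: assignments whose rank-sum deviates from
its mean at least as much as observed), which is valid under ties and is
the path checked exhaustively against a brute-force oracle in the tests.
Note the two routes differ by up to ~0.03 at group size 10 without the
continuity correction; with it they agree within 0.01.

**Logistic regression.** `preterm ~ z(paternal age) + z(maternal age) +
z(burden)`, maximum likelihood (Newton/IRLS via statsmodels, tolerance
1e-8, ≤ 100 iterations), Wald p-values, standardization means/SDs recorded
in the result. At least 10 subjects per outcome class are required;
non-convergence or coefficient divergence (|β| > 50, a separation
symptom) raises rather than returning a silently bad fit.

**Residualization.** OLS simple linear regression of counts on one
parental age; residuals (observed − fitted) sum to zero and are compared
between groups by the same rank-sum machinery. Adding any multiple of age
to all counts leaves the downstream comparison invariant (absorbed by the
fit); this is a tested property.

**Extreme load.** The top-fraction subset (default 5%) uses the k-th
largest burden with k = ceil(f·n) as threshold and includes all ties at
the threshold, so the subset never undershoots k.

**Replication timing.** For each mutation, the base-weighted mean of a
piecewise-constant timing track over a 1 kb window centered at the locus
(`[pos₀ − 500, pos₀ + 500)` in 0-based coordinates). Windows with zero
covered bases yield NaN and are excluded from group comparisons.

**Stratification.** Gestational-age bins (default [32, 37) and [20, 32))
are each compared against the term group (GA ≥ 37); bins with < 5 subjects
are flagged underpowered but still reported. All tests are two-sided by
default (one-sided alternatives available); no multiple-testing correction
is applied across the burden analyses.

## Deleteriousness and gene sets

Nonsynonymous = missense ∪ nonsense ∪ frameshift. Deleterious =
frameshift (unconditionally) or CADD phred **strictly** > 20; nonsense
variants pass through the CADD threshold rather than being
auto-deleterious, and a missing CADD score on a non-frameshift variant is
never deleterious. Raising the cutoff can only shrink the passing set;
at cutoff → ∞ only frameshifts remain (tested invariant).

Intolerance contrasts use the rank-sum test of the set's scores against
the background; when the background is "the genome", the set's own genes
are excluded from it to avoid self-comparison. Viability enrichment is a
2×2 Fisher's exact on lethal vs viable counts (subviable and unknown
excluded); degenerate margins raise with the offending margin named.
Phenotype enrichment is a one-sided hypergeometric tail per term with ≥ 1
overlap, Benjamini–Hochberg adjusted across tested terms. This is a
generic "EnrichR-analogous" reimplementation; it deliberately does not
reproduce any external tool's combined score or library versions, so
external FDR values are not comparable quantities.

## Expression propensity

Normalization across stages is per-gene z-score with sample SD (n−1) by
default (min–max behind a config key); constant rows are set to zero and
flagged. Trajectories are stage-wise mean ± SEM (SD/√n over set genes) on
normalized values. β is computed on **raw** values as mean(early-fetal
stages)/mean(postnatal stages); genes with zero postnatal mean are
excluded and counted. β is invariant to per-gene rescaling. The default
stage list is PCW 8–10, 12, 13 (early fetal), PCW 16, 17–22, 25–26 (later
fetal) and months 4, 10, 12 (postnatal); the list is configurable, and the
matrix input is assumed pre-aggregated to one column per stage. The β
contrast between two gene sets is a two-group rank-sum (each group's
median β and fraction > 1 are reported alongside, which covers the
one-sample "β > 1" reading).

## CNVR novelty

"Found in the reference" is interpreted as coverage by the **union** of
same-type reference records — the only reading invariant to record order
and fragmentation (tested). A query is shared iff covered fraction ≥ 0.8
("at least 80%"); deletion queries see only reference deletions,
duplications only duplications; an empty reference for a present type
makes those queries novel with a warning. Gene membership in a region
requires ≥ 1 bp overlap under half-open coordinates. Reciprocal-overlap
matching is out of scope (the flag structure leaves room for it).

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis targets:

| parameter | default | meaning |
|---|---|---|
| n_trios | 816 | cohort size |
| preterm_fraction | 292/816 | Bernoulli preterm label |
| paternal age | N(33.5, 5.8²) trunc ≥ 18 | years |
| maternal age | corr 0.7 with paternal, N(31.4, 4.9²) | years |
| baseline_rate a | 43.86 | E[burden] per term genome |
| preterm_shift δ | 2.22 | 46.08 − 43.86, additive |
| age_slope b | solved ≈ 0.922 | mutations per year |
| exonic_fraction | 1/50 | coding share of mutations |
| deleterious_fraction | 0.28 | P(CADD > 20 \| missense/nonsense) |
| paternal_origin_fraction | 0.80 | Bernoulli |

Burden is Poisson with rate `a + b(age − μ) + δ·preterm`, floored at one
mutation — counts of rare events per genome, matching the observed
mean ≈ variance scale; the preterm effect is additive because that is
directly calibrated by the two printed group means. The slope solves

`b = (r/σ)·√((E[λ] + δ²p(1−p)) / (1 − r²))`

for r = 0.62 with σ the paternal-age SD; the δ-variance term is a small
refinement over the pure-Poisson closed form (without it the realized
correlation sits near 0.615). Ages are centered at the analytic
truncated-normal mean so the term-group expectation equals `a` exactly.

Gestational age is a two-component truncated normal mixture: term
N(39.0, 1.2²) on [37, 45] (mean ≈ 39.1) and preterm N(33.1, 1.8²) on
[22.7, 37) (mean ≈ 33.1, with ≈ 72.6% of preterm mass in 32–37 weeks).
The component SDs are a modeling choice pinned to those three observable
quantities; the real gestational-age distribution is more heavily
left-skewed than this mixture.

Annotation: deletion intolerance is standard normal with a +0.75 SD
location shift for the causal set (duplication unshifted; combined CNV
intolerance is their scaled sum, so it inherits half the shift — the
deletion-specific signal explains the combined one); viability is
multinomial with background proportions 410:198:1143
(lethal:subviable:viable, 80% of genes having known class) and causal
lethal probability 0.45; causal genes are enriched for a nervous-system
phenotype term. Expression: fetal-biased genes decay geometrically across
the stage order (log-range 2×0.8), others flat, multiplicative lognormal
noise (σ = 0.1). Interval bundles construct shared queries at 85–100%
reference coverage and novel ones at 0–60%, with distractor reference
records placed away from every query, so the ground truth is exact by
construction.

Determinism: one global seed; each generator (cohort, mutations,
annotation, expression, intervals, region genes) derives its stream
through a fixed `SeedSequence` spawn key, so identical seeds give
byte-identical bundles across runs and platforms.

In the full bundle the causal annotation set is the genes hit by
deleterious preterm-group mutations and the fetal-biased set is the genes
placed in novel deletion regions, so every downstream stage sees the
planted signal coherently.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mutational signatures and sequence context,
non-uniform genomic position (no real replication-timing structure),
family structure/relatedness, gene length–dependent hit probability,
cohort-specific annotation pipelines, and the long left tail of
gestational age. Results on the synthetic bundle validate the inference
machinery, not any biological claim.

## Problem sizes and runtime

The default test suite runs cohorts of 816 (study size) and 10,000
(calibration checks), 200-replicate null-calibration and power batteries
at burden level (no per-mutation lists, which the tests cover separately
at study size), 500-instance interval oracles, and exhaustive rank-sum
enumeration for group sizes up to 8; the full suite completes in well
under a minute, and `scripts/acceptance.py` in a few seconds.

## Known limitations

- The exact rank-sum path enumerates C(N, m) assignments and is
  restricted to groups of ≤ 12; larger groups use the tie-corrected
  normal approximation.
- Phenotype-enrichment FDRs depend on the term universe supplied; they
  are not comparable to values from external enrichment services.
- The logistic model fits main effects + intercept only (no
  interactions), and maternal-age residualization is performed on
  maternal age alone, mirroring the paternal procedure.
- No VCF parsing, liftover, CNV calling or ortholog mapping: mutation
  lists, gene annotations and CNVRs are consumed as tabular inputs.
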