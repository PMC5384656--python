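# dnmburden

Burden and functional-consequence analysis of fetal **de novo mutations**
(DNMs) in **preterm birth (PTB)** trio cohorts.

Whole-genome sequencing of parent–offspring trios yields, for each newborn,
a list of variants absent from both parents. The central question this
package addresses is whether preterm newborns (gestational age < 37 weeks)
carry a heavier autosomal DNM burden than term newborns, and whether the
genes their deleterious DNMs hit look like genes whose disruption perturbs
early fetal (brain) development. It is written for statistical geneticists
and perinatal-genomics researchers who have trio tables and annotated DNM
calls and want the complete inference battery in one tested, scriptable
pipeline.

## What it computes

**Burden inference with confounder handling.** DNM burden is strongly
scaled by paternal age, so a naive case/control comparison is confounded.
For per-genome autosomal counts $y_i$ the package runs:

- Wilcoxon rank-sum comparison of counts between PTB and term groups
  (midranks, tie-corrected variance; exact enumeration for small groups);
- logistic regression
  $\mathrm{logit}\,P(\text{PTB}_i) = \beta_0 + \beta_1 z(\text{pat.age}_i) + \beta_2 z(\text{mat.age}_i) + \beta_3 z(y_i)$
  with z-scored predictors and Wald p-values;
- OLS residualization $y_i - (\hat a + \hat b\,\text{age}_i)$ on paternal
  (and maternal) age, followed by the rank-sum test on residuals;
- extreme-load subsets (top 5% of burden, ties included), gestational-age
  strata (e.g. 32–37 vs < 32 weeks), and mean replication timing over a
  1 kb window centered at each mutation.

**Deleteriousness filter and gene sets.** A DNM is *nonsynonymous* if
missense, nonsense or frameshift; it is *deleterious* if frameshift (by
rule) or CADD phred > 20. The deduplicated genes hit per cohort are
characterized by CNV/deletion/duplication intolerance (rank-sum vs the
genome background), mouse-knockout viability (lethal/subviable/viable
composition and a lethal-vs-viable Fisher's exact test), and phenotype-term
over-representation (hypergeometric + Benjamini–Hochberg FDR).

**Developmental expression propensity.** On a gene × stage neocortical
expression matrix, per-gene z-scored trajectories (mean ± SEM over a gene
set) and the fetal-propensity ratio

$$\beta_g = \frac{\text{mean expr}(g,\ \text{PCW 8–13})}{\text{mean expr}(g,\ \text{postnatal 4–12 mo})}$$

computed on raw values; $\beta > 1$ means fetal-biased. Gene-set $\beta$
collections are compared by rank-sum.

**CNVR novelty.** A deletion/duplication region is *shared* with a
reference collection (e.g. a population structural-variant database) if at
least 80% of its bases are covered by the union of same-type reference
records, else *novel* — evaluated type-matched on merged interval unions.

**Synthetic cohort generator.** Every input above can be generated with
the statistical structure the analysis assumes: Poisson burden with a
paternal-age slope solved in closed form for a 0.62 age–burden correlation,
a +2.22 preterm mean shift (46.08 vs 43.86), ~1 exonic mutation per 50,
80% paternal origin, intolerance shifts for a designated causal gene set,
stage-biased expression, and interval bundles with exact ground truth
(74 deletions: 64 shared / 10 novel; 57 duplications: 56 / 1).

## Worked example

```python
from dnmburden import RunConfig, run_all

summary = run_all(RunConfig(seed=1), simulate=True)
b = summary["stages"]["burden"]
print(f"term mean burden     {b['mean_burden_term']:.2f}")
print(f"preterm mean burden  {b['mean_burden_preterm']:.2f}")
print(f"rank-sum p           {b['comparison']['p_value']:.4f}")
print(f"age-burden r         {b['paternal_age_correlation']['r']:.3f}")
print(f"logistic burden coef {b['logistic']['coef']['burden']:.3f}")
print(f"deletion CNVRs       {summary['stages']['cnv']['counts']['deletion']}")
```

prints

```
term mean burden     43.35
preterm mean burden  45.22
rank-sum p           0.0085
age-burden r         0.604
logistic burden coef 0.334
deletion CNVRs       {'shared': 64, 'novel': 10}
```

Read: on this simulated 816-trio cohort the preterm group carries ~1.9
extra DNMs per genome (significant by rank-sum), paternal age explains
~36% of burden variance, burden remains the informative predictor after
adjusting for both parental ages (positive z-scored log-odds), and 10 of
the 74 deletion CNVRs are novel relative to the reference collection.

The same stages run from files via the CLI:

```bash
dnmburden --seed 1 --out-dir sim simulate
dnmburden --out-dir out burden --trios sim/trios.tsv --mutations sim/mutations.tsv
dnmburden --out-dir out cnv --query sim/query.bed --reference sim/reference.bed
dnmburden --seed 1 --out-dir out run-all --simulate
```

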