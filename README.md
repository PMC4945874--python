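# mc1rburden

Germline *MC1R* status and somatic mutation burden in melanoma exomes.

Red-hair-colour (*R*) alleles of the melanocortin-1 receptor gene are null
or strongly hypomorphic receptor variants associated with red hair, fair
skin and UV sensitivity, and they are the strongest common germline risk
factor for cutaneous melanoma.  This package implements, as a tested and
reusable pipeline, the statistical analysis that asks whether carrying an
*R* allele raises the *somatic* single-nucleotide-variant burden of the
tumour itself:

1. **Germline genotyping** — classify annotated *MC1R* coding variants as
   *R*, *r* (weakly associated missense) or wild-type, using a canonical
   lookup table, SIFT/PolyPhen predictions for rare missense variants, and
   an override table for reclassification sensitivity analyses; count
   alleles per sample (compound heterozygotes count as two).
2. **Consensus somatic calls** — keep substitutions marked PASS by at
   least two independent calling pipelines, and decompose double/triple
   nucleotide variants into component SNVs.
3. **Mutation spectra** — pyrimidine-normalized six-class and
   96-trinucleotide-context counts per sample.
4. **Burden regression** — for each substitution class, negative-binomial
   (NB2) regression with a log link,

       log E[y_i] = β₀ + β_R·1(R_i ≥ 1) + β_age·age_i + Σ_k β_k x_ik,
       Var[y_i] = μ_i + μ_i²/θ,

   adjusted for clinical covariates, with missing clinical data multiply
   imputed by chained equations (m = 10), estimates pooled by Rubin's
   rules, and the six per-class *R*-allele p-values Benjamini–Hochberg
   adjusted.  Effects are reported as multiplicative percent changes,
   100·(e^β − 1), and the *R*-allele effect is also expressed as an **age
   equivalence** β_R / β_age — the extra years of aging with the same
   modelled mutational burden.
5. **Mutational signatures** — a hierarchical Dirichlet process mixture
   over the 96 contexts on a sample → *R*-group → root tree, sampled by
   collapsed Gibbs with Chinese-restaurant-franchise bookkeeping, with
   component consolidation across posterior samples and credible-interval
   contrasts of group-level exposures.
6. **Synthetic cohorts** — a first-class generator emulating the two
   study cohorts (a TCGA-like collection, n = 273, eight covariates, ~12%
   missing-at-random clinical data; a Yale-like collection, n = 132,
   three complete covariates), so every stage is testable end to end with
   no controlled-access data.

The intended users are statistical-genetics and cancer-genomics analysts
who want to rerun, stress-test or extend this class of burden analysis on
their own cohorts or on simulations.

## Worked example

Generate a Yale-scenario synthetic cohort (n = 132, C>T rate ratio 1.58
for *R*-presence as ground truth), genotype it from emitted germline
records, and fit the six-class burden model:

```python
from mc1rburden import (
    yale_config, generate_cohort, emit_germline_variants, genotype_cohort,
    summarize_genotypes, ModelSpec, run_burden_analysis,
)

cfg = yale_config(seed=7)
cohort, truth = generate_cohort(cfg)
genotypes = genotype_cohort(emit_germline_variants(truth, seed=7),
                            all_samples=list(cohort["sample_id"]))
freq = summarize_genotypes(genotypes)
print(freq[freq.level_type == "r_count"].to_string(index=False))

spec = ModelSpec(covariates=("age", "sex", "sample_type"))
analysis = run_burden_analysis(cohort, spec, m=1, seed=0)
print(analysis.table().round(3).to_string(index=False))
```

which prints

```
level_type level  count  percent
   r_count     0     74       56
   r_count     1     53       40
   r_count     2      5        4

class      term  percent_change  ci_low  ci_high  p_raw  p_adjusted  age_equivalence_years
  C>A r_present          98.202  37.117  186.499  0.000       0.001                 30.997
  C>G r_present          50.145   4.806  115.096  0.027       0.032                 18.176
  C>T r_present          97.607  46.378  166.766  0.000       0.000                 41.997
  T>A r_present          69.031  23.200  131.912  0.001       0.002                 38.964
  T>C r_present         112.875  48.074  206.034  0.000       0.000                 40.983
  T>G r_present          15.568 -20.971   69.001  0.453       0.453                 12.755
```

The genotype table shows the simulated cohort's *R*-allele frequencies
(56/40/4% with 0/1/2 alleles).  Each row of the effect table is one
substitution class: `percent_change` is the estimated multiplicative
change in expected SNV count for *R*-carriers versus non-carriers with
its 95% CI, `p_adjusted` is the BH-corrected p-value across the six
classes, and `age_equivalence_years` converts the *R* effect into years
of aging.  On a single cohort the per-class estimates scatter widely
around the generative truth (58% for every class here) because melanoma
SNV counts are strongly overdispersed (θ = 1); replicate averaging, as in
the acceptance script, recovers the configured effects.

The same stages are available from the shell:

```sh
mc1r-burden simulate --scenario yale --seed 7 --out out/
mc1r-burden burden --cohort out/cohort.tsv --mode six_class --m 10 --seed 0 --out out/burden.tsv
mc1r-burden run --scenario combined --n-samples 60 --profile demo --seed 1 --out out/run/
```

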