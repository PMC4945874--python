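# Methods

This note documents the models, the synthetic-data calibration, the
numerical choices, and the known limitations of `mc1rburden`.

## Germline MC1R allele classification

Variants are classified in strict precedence order: explicit overrides →
canonical lookup table → consequence rules → predictor rule.

* The canonical table (`data/mc1r_canonical.tsv`, configurable) carries
  the consensus literature assignment of the nine canonical *MC1R*
  missense polymorphisms: R = {p.Asp84Glu, p.Arg142His, p.Arg151Cys,
  p.Arg160Trp, p.Asp294His}; r = {p.Val60Leu, p.Val92Met, p.Ile155Thr,
  p.Arg163Gln}.  It is shipped as data, not code, because these
  assignments are empirical conventions that users may wish to edit.
* Nonsense and frameshift variants are R (protein-truncating alleles are
  null); synonymous and other non-coding-change consequences are
  wild-type.
* Rare missense variants are resolved from SIFT and PolyPhen: both
  damaging → R; exactly one damaging → r; both benign → wild-type; both
  unavailable → "unresolved", excluded from allele counting with a
  logged warning.  This rule is monotone in predictor severity.  It is a
  documented stand-in — the exact published decision tree is not
  reproduced here — and the override table lets any variant-level
  decision be forced (e.g. p.Thr95Met → r, p.Arg213Trp → R for the
  functional-assay-informed sensitivity analysis).
* Per-sample counting: hom contributes 2 alleles, het 1, capped at two
  total.  Two distinct het R variants are treated as a compound
  heterozygote (R/R): without phased reads cis configurations cannot be
  excluded, and the trans assumption is adopted deliberately.  When the
  cap binds, R alleles take precedence over r, since disruptive alleles
  drive the phenotype of interest; every cap application is logged.

Reported genotype percentages are rounded half-up to integers, matching
how cohort frequencies are conventionally printed.

## Consensus somatic calls and MNV decomposition

A call is retained when at least `min_callers` (default 2) pipelines
called it *and* each supporting pipeline marked it PASS — the strictest
reading of a "PASS and called by ≥2 centres" rule; a non-PASS record
contributes no support.  Consensus is monotone: lowering `min_callers`
never removes calls.

Multi-base substitution records of length 2–3, and runs of adjacent
(1 bp apart, same sample and contig) single-base calls, are decomposed
into component SNVs, each tagged with its MNV of origin.  By default a
DNV therefore adds **two** to every burden count (and a TNV up to
three), which keeps the per-context spectra consistent with the SNV
counts; the tags allow the alternative convention (one count per MNV) to
be recomputed downstream.  Decomposition conserves base changes: the
number of emitted SNVs equals the number of altered bases.

## Mutation spectra

Substitutions are normalized so the reference base is a pyrimidine
(purine-reference changes are reverse-complemented together with their
flanks), giving six classes (C>A, C>G, C>T, T>A, T>C, T>G) and 96
trinucleotide contexts.  The 96-category layout is class-major with the
5' flank as the outer key and the 3' flank inner, both in A,C,G,T order —
the conventional layout of published signature matrices, so component
vectors are directly comparable with external catalogues.  Spectra files
carry explicit context headers ("A[C>T]G") to make the dialect
self-describing.  Trinucleotide contexts come either from a provided
column or from a FASTA (pyfaidx random access); contig-edge variants are
excluded with a warning.

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes;
they are fixed once and are not tuning knobs.

* **Genotypes**: 0/1/2 R alleles with probabilities (0.505, 0.411,
  0.084) in the TCGA-like scenario, (0.553, 0.409, 0.038) in the
  Yale-like scenario, (0.521, 0.410, 0.069) combined — the observed
  cohort frequencies.
* **Covariates**: age truncated-normal(58, 14) on [20, 95] years,
  matching the reported median 57 (IQR 46–70); sex P(male) = 0.64;
  collection-centre, body-area, Clark-level and sample-type categoricals
  at the reported cohort marginals (renormalized over known categories);
  ulceration probability 0.46; Breslow depth log-normal(log 2.5, 1.06)
  mm, matching the reported median 2.5 mm and IQR 1.2–5.0.
* **Counts**: per class c, y ~ NB2 with mean
  exp(β₀c + β_R·1(R≥1) + β_age·(age − 57) + …) and size θ, drawn as a
  gamma–Poisson mixture — the same family the regression fits.  Scenario
  ground truths for the C>T class are rate ratio 1.24 (TCGA-like), 1.58
  (Yale-like), 1.42 (combined), age effect 1.017/year; all six classes
  share the scenario effect, reflecting the reported "similar
  enrichment" across classes.  Baseline per-class means at reference
  covariates are (35, 25, 250, 15, 30, 10) for (C>A, C>G, C>T, T>A,
  T>C, T>G) — realistic melanoma-exome magnitudes with C>T dominant.
* **Dispersion** θ = 1.0 per class.  The published per-class dispersions
  are not printed; θ = 1 is this package's own calibration chosen so the
  simulated Wald CI widths match the printed intervals (e.g. the
  combined C>T interval 15–76% implies a log-scale SE ≈ 0.109 at
  n = 405, which NB2 sampling with θ ≈ 1 reproduces).
* **Context structure**: each class count is split multinomially over
  that class's 16 contexts according to the R-group's signature mixture.
  Three stylized profiles are built programmatically (UV-like C>T at
  5'-pyrimidines, ageing-like C>T at CpG, broad background), with group
  exposures (0.55, 0.25, 0.20) for non-carriers and (0.65, 0.15, 0.20)
  for carriers — the carriers' lower ageing-signature weight mirrors the
  reported group difference.  These are illustrative profiles, not
  catalogue signatures.
* **Missingness**: ~12% of clinical cells, MAR-on-age by default — cell
  masking probability logistic in standardized age (slope 0.5), with the
  intercept calibrated by bisection to the target marginal rate.  This
  exercises imputation under a non-MCAR mechanism without extremity.
  Age itself, being the conditioning variable, is masked MCAR at the
  same rate (masking age on its own value would be MNAR).  Genotypes and
  mutation counts are never masked.
* **Caller noise**: per-caller false-negative dropout is Bernoulli per
  true call; fabricated calls are Poisson(fp_rate · n_true),
  caller-private, and flagged, so consensus precision can be scored.
* **MNVs**: off by default; `spectra_to_calls(dnv_fraction=…)` pairs a
  fraction of C>T calls into adjacent positions (count-conserving) to
  exercise decomposition.

What the generator does **not** emulate: genomic position structure
(calls are placed on a synthetic contig), indels, sequencing depth and
allele-fraction noise, centre-specific mutation-rate differences (centre
effects default to zero), correlation between covariates and genotype,
and real signature catalogues.  Passing recovery tests therefore shows
the estimator chain is correct under the assumed generative model, not
that the published point estimates are reproduced from real data — the
real cohorts are controlled-access and deliberately not required.

## Burden regression

* **Imputation** is chained equations, m = 10 by default, five sweeps:
  predictive mean matching (5 donors, Bayesian coefficient draw) for
  continuous variables, logistic draws for binary, polytomous logistic
  draws for categorical.  Every univariate model uses the other clinical
  covariates, R presence, and log1p of the six class counts as
  predictors (counts are predictors of missingness-relevant severity;
  the log1p transform stabilizes the logistic fits).  Any categorical
  level carried by fewer than five samples is set to missing and imputed
  away before the sweeps.  Breslow depth is imputed and modelled on the
  log scale (heavy-tailed positive variable); this is switchable.
  Complete data short-circuits to m identical copies, making pooling
  with complete data exactly equal to a single fit.
* **NB2 fits** maximize the joint likelihood over coefficients and
  dispersion (statsmodels, α = 1/θ), seeded from a Poisson fit, trying
  BFGS → Newton → Nelder–Mead and raising a ConvergenceError with the
  method trace if none converges.  SEs are Wald from the observed
  information.  Wald (not profile) intervals are used throughout — the
  published choice is unstated; Wald is the documented default.
* **Design**: intercept; R presence (0/1) or count (dummies for 1 and 2
  alleles); age in years; categoricals dummy-coded against fixed
  reference levels (centre reference "EE", the University of Sydney —
  the published baseline centre; sex F; sample type metastasis; body
  area extremities; Clark IV).  Zero-variance dummies are dropped;
  rank-deficient designs raise an error rather than silently pinning
  coefficients.
* **Pooling**: Rubin's rules with total variance W + (1 + 1/m)B and
  Barnard–Rubin small-sample degrees of freedom (complete-data df
  = n − p); two-sided t p-values.  With B = 0 the df reduce to n − p.
* **Multiplicity**: BH step-up across the six classes, applied to the
  R-term p-values in six-class mode only; 95% CIs and a 0.05 threshold
  on adjusted p throughout.
* **Age equivalence** = β_R / β_age, the ratio of log rate ratios.  With
  the printed estimates log(1.42)/log(1.017) = 20.8 ≈ 21 years.
* **No exposure offset**: exome footprint is treated as constant across
  samples, matching a raw-count analysis.
* Count mode (three genotype levels) reports each level's contrast
  separately; when a cohort has no 2-R samples the `r_count_2` dummy
  drops out and count mode coincides with presence mode.

## HDP signature model

Each mutation is a draw from a sample-specific mixture over latent
96-category components.  The tree is root → two R-group DPs → one DP per
sample; the root base measure is a uniform Dirichlet (per-category
pseudocount η = 1, configurable).  Concentration parameters are shared
per tree level with Gamma(1, 1) hyperpriors — the published analysis
defers these to its software defaults, so this is the package's own
documented choice.

The sampler is direct-assignment collapsed Gibbs: per-item cluster
reassignment under node predictive weights, where the weights at every
node are refreshed once per iteration from Chinese-restaurant-table
(CRT) resampled table counts propagated leaf → group → root, and
concentrations are updated with the Escobar–West auxiliary-variable
scheme.  Component emission probabilities are integrated out
analytically.  New clusters born mid-sweep receive geometric
stick-breaking shares of the current new-cluster mass until the next
weight refresh.  Empty clusters are compacted every iteration.  The
item sweep and CRT loops are numba-compiled; all randomness flows from a
master `SeedSequence`, with one spawned stream per chain, so runs are
exactly reproducible.

Profiles: the published settings (4 chains, 10,000 burn-in, 500 samples
per chain at spacing 50, 4 initial clusters) are the default
`SamplerConfig`; `desk_profile()` (2 chains, 500 burn-in, 50 samples at
spacing 10) is sized for tests and interactive use.  Redundant initial
clusters merge slowly under collapsed Gibbs (a known CRP mixing
property), so short-burn-in runs can transiently carry an extra cluster;
the test suite uses burn-ins long enough for desk-scale data sizes.

Extraction: clusters are matched across posterior samples to a running
registry by cosine similarity ≥ 0.90 (largest clusters matched first,
one registry entry per posterior sample); entries present in ≥ 50% of
posterior samples are retained.  Component vectors are posterior means
with 2.5/97.5% quantile bands; exposures are per-node assigned-data
fractions with the unmatched remainder reported as unassigned mass.
Both the matching threshold and the retention rule are documented
stand-ins for the referenced software's unpublished heuristic.  Group
contrasts are flagged significant when the two groups' 95% credible
intervals are disjoint; the published significance criterion is
unstated, and disjoint intervals are a conservative choice.

## Pipeline and reproducibility

One master seed spawns independent per-stage streams
(simulate/callers/germline/burden/signatures), so the full pipeline
report is byte-identical across reruns (no timestamps in the payload).
Tabular outputs are TSV with a provenance header comment (seed, config
digest); the report is JSON with a fixed key schema.

## Problem sizes

The acceptance script averages the pooled C>T percent-change estimate
over 25 combined-scenario cohorts (n = 405, m = 10) for the R and age
effects, 50 Yale-scenario cohorts (n = 132, complete data) and 50
TCGA-scenario cohorts (n = 273, m = 10).  At θ = 1 the per-replicate
estimator SD is ≈ 15 percentage points for the R effect, so the
replicate averages carry a Monte-Carlo SE of ≈ 2–3 points.  Test-suite
simulations use fewer replicates and smaller sampler settings, chosen as
desk-scale sizes with comfortable margins relative to their Monte-Carlo
error.

## Known limitations

* The SIFT/PolyPhen combination rule and the HDP extraction heuristic
  are documented stand-ins for unpublished decision procedures.
* Indels, structural variants and phasing are out of scope; compound
  heterozygosity is assumed for multi-variant carriers.
* The burden model fits raw counts with no exome-size offset and no
  zero-inflation; quantile and zero-inflated alternatives are not
  provided.
* Published point estimates from the real cohorts are not reproduced
  here — they require controlled-access data; the package demonstrates
  estimator correctness on calibrated simulations instead.
* The HDP sampler refreshes node weights once per sweep rather than
  after every item; this is a standard and much faster approximation of
  the fully sequential franchise scheme, and its recovery behaviour is
  validated in the test suite.
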