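# aim-mr

Instrumental-variable analysis of **genetic-ancestry proportion as an
exposure**, for epidemiologists and statistical geneticists working with
admixed populations. The motivating setting is an admixed Latin American
population in which the individual proportion of one indigenous ancestry
component is suspected of driving disease risk: observational associations
between ancestry proportion and disease are confounded by socio-economic
factors, health-care access, and unknown risk factors, but the alleles of
ancestry-informative markers (AIMs) are randomized at meiosis, so AIMs can
serve as instrumental variables for the ancestry proportion in a Mendelian
randomization (MR) design.

The package implements the full analysis chain:

1. **AIM preselection** — Rosenberg's informativeness for assignment,

   *I*<sub>n</sub> = Σ<sub>j</sub> −p̄<sub>j</sub> ln p̄<sub>j</sub> +
   Σ<sub>i</sub> Σ<sub>j</sub> (p<sub>ij</sub>/K) ln p<sub>ij</sub>,

   evaluated pairwise (target population against each other reference
   population), with the per-comparison top-k union retained.
2. **Supervised admixture** — per-individual maximum-likelihood ancestry
   proportions against fixed reference-panel allele frequencies, via the
   standard EM fixed point on the K-simplex (the model supervised
   ADMIXTURE fits).
3. **Instrument construction** — exposure GWAS (ancestry % on dosage,
   age/sex-adjusted), genome-wide relevance filter (p < 5×10⁻⁸), static
   exclusion-list (PheWAS stand-in) filter, per-variant explained variance
   β²·2·MAF·(1−MAF) on the standardized exposure scale, greedy LD pruning
   (r² ≤ 0.01), optional Steiger directionality filter, and joint /
   per-instrument F statistics.
4. **Two-sample MR** — harmonization (allele alignment, palindromic
   removal), random-effects IVW with first-order weights, Cochran's Q,
   MR-Egger, weighted median (bootstrap SE), and radial MR outlier
   excision, all from closed forms.
5. **Mediation** — two-step MR (computed stage 1, user-supplied published
   stage 2) and multivariable MR (WLS of outcome betas on several exposures'
   betas, Sanderson-style conditional F per exposure).
6. **Stratification sensitivity** — Eigenstrat-normalized genotype PCA with
   all-PCs or leave-out-the-ancestry-PC adjustment modes.
7. **Synthetic cohorts** — Balding–Nichols reference panels, Dirichlet
   individual ancestry, binomial genotypes, and prospective logistic /
   linear outcomes with per-1%-ancestry effects; every downstream stage is
   testable without access to protected cohort data.

Ancestry proportions are carried on the percent scale throughout, so every
effect is "per 1% increase in the target-ancestry proportion" and odds
ratios are directly comparable with how admixture-exposure studies report
them.

## Worked example

Run the complete synthetic study — panel → AIM preselection → supervised
admixture → exposure/outcome GWAS → filter cascade → radial MR → estimator
suite — from the command line:

```bash
aim-mr pipeline --seed 1 --out results/run1
```

The stage ledger (`results/run1/stage_ledger.tsv`) records every filter:

```
stage             threshold  n_in   n_out
in_preselection   300        1000   578
relevance         5e-08      578    301
phewas_exclusion  5e-08      301    301
ld_pruning        0.01       301    202
harmonization     drop       202    202
radial_outliers   0.05       202    192
```

and `results/run1/results.json` holds the estimator rows (this run used
1,861 exposure-sample individuals, 412 case-control pairs and a true odds
ratio of 1.008 per 1% ancestry):

```
ivw              OR 1.0100  95% CI 1.0067-1.0133  p 3.0e-09  Q p 0.99  intercept p 0.51
egger            OR 1.0154  95% CI 0.9992-1.0318  p 0.063
weighted_median  OR 1.0102  95% CI 1.0055-1.0149  p 2.1e-05
```

The IVW odds ratio is the inverse-variance-weighted mean of the
per-instrument Wald ratios, exponentiated; Q and Egger-intercept p-values
near the top of their range indicate no detectable heterogeneity or
directional pleiotropy (as expected here: the simulated outcome depends on
ancestry only, through no pathway the instruments could short-circuit).
The slight overshoot of the point estimate relative to the generating OR
of 1.008 comes from using the EM-estimated (rather than true) ancestry as
the exposure — see the measurement-scale note in `docs/methods.md` — which
is why estimator calibration and CI coverage are assessed over replicates
against the true exposure (see below), not from a single run.

The same estimators run on deposited-format summary-statistics files
(columns `variant, effect_allele, other_allele, eaf, beta, se, p, n`):

```bash
aim-mr mr --exposure exposure.tsv --outcome outcome.tsv \
      --method ivw,egger,wmedian --radial-alpha 0.05 --palindromic drop \
      --exponentiate --seed 7 --out mr.json
```

which writes the result JSON plus a harmonization audit
(`mr.audit.tsv`) listing every variant's fate (kept / flipped /
removed-palindromic / removed-incompatible). `aim-mr mvmr` fits the
multivariable model from three summary files, and `aim-mr simulate`,
`informativeness`, `admixture`, `gwas`, `instruments` expose the individual
stages.

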