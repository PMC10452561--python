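# Methods

This note documents the statistical models the package implements, the
synthetic data-generating process used to exercise them, the numerical
choices, and the limits of what the test suite demonstrates.

## The analysis the package implements

The exposure is the individual proportion of one target ancestry component
in an admixed population, carried on the percent scale (each individual's
components sum to 100). Because ancestry proportion is fixed at conception
while the alleles of ancestry-informative markers (AIMs) are randomized at
meiosis, AIMs strongly associated with the ancestry proportion can act as
instrumental variables: their association with a disease outcome, scaled by
their association with the ancestry proportion, estimates the
confounding-free effect of ancestry on the outcome. The analysis is
two-sample: instrument–exposure associations come from one cohort
(sample I), instrument–outcome associations from another (sample II).

### Marker informativeness

For a biallelic variant with effect-allele frequency p_i in population
i = 1..K, the informativeness for assignment is

    I_n = sum_j [ -pbar_j ln pbar_j ] + sum_i sum_j (p_ij / K) ln p_ij

with j over the two alleles and pbar_j the unweighted mean of p_ij over
populations, using the 0·ln 0 = 0 convention. I_n is in nats, vanishes iff
all populations share a frequency, and reaches ln K at a fixed difference.
pbar is deliberately the unweighted average: reference panels typically
have very different population sample sizes, and weighting by panel size
would let the largest panel dominate the ranking. Comparisons run pairwise
(target vs. each other population, K = 2 per evaluation); the per-comparison
top-k sets are unioned. Ranking ties break by variant id so the selection is
deterministic.

### Supervised ancestry estimation

Given fixed panel frequencies p_km (clamped to [1e-3, 1-1e-3]), each
individual's ancestry vector q on the K-simplex maximizes the binomial
log-likelihood sum_m [ g_m ln f_m + (2-g_m) ln(1-f_m) ], f_m = sum_k q_k
p_km, with missing genotypes dropped from the sum. The maximizer is found
by the EM fixed point

    q_k <- q_k / (2M) * sum_m [ g_m p_km / f_m + (2-g_m)(1-p_km) / (1-f_m) ]

initialized at the uniform simplex point, with tolerance 1e-6 log-likelihood
units and a 2,000-iteration cap. EM was chosen over quasi-Newton because the
update preserves simplex feasibility by construction and its monotonicity is
asserted at every iteration. EM converges sublinearly when a component
approaches the boundary q_k = 0, so a small fraction of individuals can hit
the iteration cap with a still-shrinking gain; they are flagged
`converged = False`. Individuals that reach the tolerance are frozen, which
keeps the per-iteration cost proportional to the unconverged set. Identical
(collinear) reference populations are detected and warned about: only the
sum of the collinear components is identifiable. Estimates are validated by
recovery on simulated cohorts, not by byte-comparison to the ADMIXTURE
software, whose acceleration internals differ.

### Instrument construction

The exposure scan regresses ancestry percent on each variant's dosage plus
age and sex (and optionally genotype PCs), using one QR-based
Frisch–Waugh–Lovell projection so the per-variant slope, SE and t-test are
exactly the full-model OLS quantities. Binary outcome scans use
maximum-likelihood logistic regression, batched across variants (all
variants share the covariate block, so each Newton step is one stacked
(M, p, p) solve); the batched fit is verified against statsmodels per-variant
fits in the test suite. Monomorphic variants and (quasi-)separated logistic
fits are flagged and excluded with a logged reason.

The filter cascade — relevance p < 5e-8, static exclusion-list filter
(standing in for a PheWAS lookup; p < 5e-8), greedy LD pruning at r² ≤ 0.01
on squared Pearson dosage correlation with priority given to larger
explained variance, optional Steiger directionality filter, single-pass
radial-MR outlier excision at alpha 0.05 — writes a ledger of
(stage, threshold, n_in, n_out) records whose counts must reconcile.
Stricter sensitivity presets (LD r² ≤ 1e-3, exclusion p < 5e-6) are plain
config values.

Per-variant explained variance uses beta² · 2 · MAF · (1 − MAF) with beta on
the standardized (unit-variance) exposure scale, so each value is a variance
proportion. Two aggregate strength summaries are computed, because they
genuinely differ: the **joint R²** from regressing the exposure on all
retained instrument dosages simultaneously (bounded in [0, 1), feeding the
joint F = R²/(1−R²) · (n−k−1)/k), and the **sum of per-variant values**
together with the mean per-instrument F (mean squared t). On ancestry
exposures the per-variant values share the latent ancestry factor, so their
sum can exceed 1 even after LD pruning; the joint R² is the interpretable
variance proportion and is what `total_r2` reports.

Steiger filtering keeps an instrument iff its exposure r² (from the t²
identity t²/(t²+n−2)) exceeds its outcome r². For binary outcomes the
observed-scale r² is approximated by linearizing the logistic model at the
case fraction c: r² ≈ lor² · c(1−c) · 2f(1−f). This is a documented
approximation, adequate for a directionality comparison; variants with
missing outcome EAF cannot be scored and are retained with a warning flag.

### Two-sample MR estimators

All estimators consume harmonized per-instrument betas. Harmonization
aligns the outcome record to the exposure's effect allele (sign flip +
EAF complement when swapped), removes incompatible allele pairs, and
handles palindromic (A/T, C/G) variants by policy: `drop` (default)
removes them all; `maf` retains those with MAF < 0.3 on both sides;
`keep` retains everything. Every decision is written to an audit table.

With Wald ratios r_i = beta_out,i / beta_exp,i and first-order standard
errors se_i = se_out,i / |beta_exp,i|:

* **IVW**: estimate = Σ w_i r_i / Σ w_i with w_i = 1/se_i², identical to
  WLS-through-origin of outcome on exposure betas weighted by 1/se_out².
  Multiplicative random effects inflate the fixed-effect SE by
  sqrt(max(1, Q/(L−1))) — never deflate — which is what keeps the type I
  error controlled under the causal null; p from the normal.
* **Cochran's Q**: Σ w_i (r_i − estimate)², chi-square on L−1 df, a proxy
  for pleiotropy-driven heterogeneity.
* **MR-Egger**: after orienting exposure betas positive, WLS of outcome on
  exposure betas with an intercept; the slope is the causal estimate and
  the intercept the mean directional pleiotropy; t inference on L−2 df
  with the same multiplicative inflation.
* **Weighted median**: cumulative-weight interpolation at 50% of the
  inverse-variance weights; consistent when ≥50% of weight is valid; SE by
  seeded parametric bootstrap (default 1,000 resamples of both betas).
* **Radial MR**: the IVW fit in radial coordinates; per-instrument
  contributions Q_i = w_i (r_i − estimate)² sum exactly to the global Q;
  instruments with chi-square(1) p < alpha (default 0.05) are excised in a
  single pass and the model refit once. Single-pass excision is the
  documented default; iterated refitting is deliberately not performed.

### Multivariable MR and mediation

MVMR fits WLS of outcome betas on the k exposures' beta columns without
intercept, weights 1/se_out² (first-order throughout, consistent with the
univariable module), normal p-values, and the same multiplicative SE
inflation. Collinear exposure columns (condition number > 1e8) abort with
an explicit error; an all-zero column is dropped with a warning so the fit
reduces to the nested model. Heterogeneity Q uses L−k df. Per-exposure
instrument strength is a Sanderson-style conditional F: exposure j's betas
are regressed on the other exposures' betas (weights 1/se_xj²) and
F_j = Q_xj / (L − k + 1); with a single exposure this reduces exactly to the
mean per-instrument F, and duplicated exposures give F ≈ 0. Values below 10
are flagged weak.

Two-step mediation reports a computed stage 1 (ancestry → mediator IVW) and
a user-supplied published stage 2 (mediator → outcome), with provenance
recorded; the package does not estimate mediation proportions — direct and
total effects only.

### Genotype PCA

Eigenstrat normalization (centre by 2p̂, scale by sqrt(2p̂(1−p̂)); variants
below MAF 0.01 or fully missing dropped; residual missingness
mean-imputed), truncated SVD, deterministic sign convention (largest-|loading|
variant positive per component). The stratification sensitivity analysis
either adjusts the association scans for all ten leading PCs or for all but
the component most correlated (|r|) with the exposure — in an admixed cohort
that component tracks the target-ancestry gradient, so conditioning on it
removes the exposure signal by construction; the selected component index is
logged rather than hardcoded.

## Synthetic data-generating process

The generator emulates a four-way admixed population with
Mapuche/Aymara/European/African-like roles:

* **Reference panel**: ancestral frequency per variant uniform(0.05, 0.95);
  population frequencies Balding–Nichols beta draws with dispersion F
  (`divergence`); all frequencies clamped to [0.01, 0.99] so no marker is
  fixed and no I_n term degenerates. F = 0 is the exact zero-dispersion
  limit.
* **Individuals**: ancestry q ~ Dirichlet(alpha), default alpha
  (4, 2, 3, 0.5) — a target-dominated gradient with a minor African-like
  component; genotypes Binomial(2, Σ_k q_k p_km).
* **Outcomes**: binary disease on the log-odds scale,
  logit P = logit(prevalence) + theta_b · q_target(%) + small age/sex
  terms, defaults theta_b = 0.008 (OR 1.008 per 1%) and prevalence 0.10;
  continuous trait 25 + theta_c · q_target + N(0, 1), default theta_c =
  −0.006 per 1%. Binary cohorts are simulated prospectively and then
  down-sampled to a matched case-control design (default 412 pairs); the
  case sampling fraction is returned for logging.

All randomness flows through one seeded `numpy` generator per stage; equal
seeds give bit-identical output.

What the generator does **not** emulate: haplotype-level local ancestry,
linkage maps, realistic LD blocks (LD enters only as correlated/duplicated
variants for pruning tests), genotyping error, and population-specific
covariate distributions. Consequently, passing tests demonstrate estimator
correctness and calibration under the assumed model — not robustness to
real-data artefacts such as local-ancestry switch errors or fine-scale LD
with causal variants.

## Replicate-study designs and why their knobs are set as they are

Two properties are verified by replicate simulation; their designs were set
by an a-priori power and identifiability analysis and then frozen.

**IVW calibration and coverage** (200 replicates each arm): exposure sample
n = 2,000, 400 case-control pairs, 40 candidate variants at divergence 0.2
of which ~12 pass the 5e-8 relevance filter. Under theta = 0 the rejection
rate at alpha 0.05 must sit inside the binomial envelope [0.021, 0.088];
under theta = log(1.03) the 95% CI must cover in ≥90% of replicates. These
replicates use the *true* simulated ancestry as exposure, isolating
estimator calibration from admixture-estimation error (recovery of the
estimated ancestry is tested separately). The instrument density matters: a
genetic-ancestry exposure makes all AIM instruments mutually correlated
through the ancestry gradient, and as the set of strong instruments
saturates the outcome sample's information the nominal first-order IVW SE
understates the true sampling variance and coverage degrades. With ~12
moderate instruments the nominal and true variance agree well. This
saturation effect is a genuine limitation of ancestry-proportion MR, not of
the implementation, and is worth keeping in mind when hundreds of strong
AIMs are used on small outcome samples.

**Complete-mediation signature** (200 replicates): ancestry → mediator →
outcome chain with no direct path. The mediator is a binary diagnosis with
prevalence 0.5 whose liability rises by 0.072 log-odds per 1% target
ancestry; the outcome depends on the mediator's *liability* (coupling 0.11
per log-odds unit) rather than the dichotomized status — disease burden, of
which diagnosis is a noisy indicator, carries the downstream risk — so the
implied total effect is ≈ 0.072 × 0.11 ≈ 0.008 log-odds per 1%, matching
the effect size the package's headline pipeline simulates. Five dedicated
mediator instruments (log-OR 0.5 each) anchor the mediator column. Sample
sizes: 1,861 exposure individuals, 6,000 mediator-GWAS pairs, 4,500
outcome pairs. The mediator GWAS is deliberately large: MVMR is an
errors-in-variables regression, and when the mediator betas are measured
with noise comparable to their spread, the attenuation leaks mediated
signal into the ancestry column and produces spurious direct effects. The
chosen size keeps the mediator-beta reliability above 0.95, making complete
mediation identifiable: the univariable ancestry → outcome IVW is
significant while the MVMR direct ancestry effect stays within |z| < 2,
each in ≥90% of replicates. At literal small-study scale (a few hundred
pairs) the signature is not reliably recoverable — conditional F values are
then in the low single digits and the direct-effect estimate is dominated
by attenuation leakage — which is the quantitative reason MVMR results from
weak-instrument settings deserve caution.

## Numerical choices and degenerate inputs

* Natural logarithms throughout I_n (ranks are base-invariant anyway).
* Panel frequencies clamped to [1e-3, 1−1e-3] before likelihood evaluation;
  generator frequencies to [0.01, 0.99].
* Monomorphic variants: beta 0, se ∞, p 1, flagged, excluded downstream.
* Logistic separation: flagged when the dosage coefficient exceeds 15 in
  absolute value or Newton fails to converge (damped steps, 50-iteration
  cap); flagged variants are excluded with a log entry.
* LD pruning ties and I_n ranking ties break by variant id.
* Weighted-median interpolation uses mid-point cumulative weights; the
  bootstrap seed is mandatory in the pipeline config.
* CI bounds use z = 1.959963984540054 (normal) or the exact t quantile
  (Egger).
* Missing dosages are mean-imputed inside GWAS scans and PCA; the
  admixture likelihood drops them instead (no imputation where the model
  handles missingness exactly).
* `run_pipeline` writes a `FAILED` marker into the output directory before
  writing results and removes it on success, so partial bundles are
  detectable.

## Known limitations

* First-order weights ignore exposure-beta uncertainty; with very weak
  instruments the IVW estimate attenuates toward the null (two-sample
  design), and the calibration study documents the SE-understatement that
  appears when many correlated instruments saturate a small outcome sample.
* Using EM-estimated ancestry as the exposure compresses the exposure scale
  slightly relative to truth (shrinkage toward the simplex interior), which
  inflates Wald ratios by the inverse factor; at the default panel
  divergence this bias is small (≈0.2 percentage points on an OR of 1.008
  in the worked example) but it is visible, and effect sizes from estimated
  ancestry should be read with that in mind.
* The binary-outcome Steiger r² and the liability-scale mediation chain use
  documented linearizations; both are approximations chosen for
  determinism and transparency.
* No haplotype-level or local-ancestry modelling anywhere.
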