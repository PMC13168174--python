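# Methods

`soyclass` implements a classification-based genomic prediction workflow for
early-stage soybean advancement decisions: sparse multi-environment yield
trials are summarised into a check-referenced selection index per breeding
line, lines are binned into three yield classes, and multinomial classifiers
trained on SNP markers predict those classes — so that lines with a high
predicted probability of being low-yielding can be discarded before they
consume field-testing capacity.

## The multi-environment genomic mixed model

Yield records at the genotype × environment (BLUE) level follow

    y_{lyg} = μ + L_l + (L:Y)_{ly} + u_g + w_{lg} + ε_{lyg}

* `u ~ N(0, σ²g G)` — additive genomic effects, with `G` the VanRaden
  realized relationship matrix `ZZ′ / (2 Σ p_j (1 − p_j))` computed from
  {0,1,2} marker codes centered at `2p_j`.
* `w_{lg} = λ_l f_g + δ_{lg}` — a factor-analytic order-1 (FA1)
  genotype-by-location term: each location loads with `λ_l` on one latent
  environmental gradient, `f_g` is the line's sensitivity to it, and
  `δ_{lg} ~ N(0, ψ_l)` is a location-specific deviation.  Jointly
  `w ~ N(0, (ΛΛ′ + Ψ) ⊗ G)`: the genotype dimension of the interaction also
  carries the genomic covariance.
* `ε` — iid residual (on the per-environment BLUE scale).  Plot-level input
  is reduced to per-environment genotype means first (configurable).

The fixed part `μ + L_l + (L:Y)_{ly}` saturates the environment means, so it
is fitted as one mean per environment and decomposed afterwards under a
sum-to-zero convention.  Environments within a location share that
location's loading; a documented switch (`FitOptions.ly_random`) treats the
location-by-year term as random instead.

**Estimation.**  Because every random term carries `G` across genotypes, the
marginal covariance between records i and k collapses elementwise to
`(σ²g + λ_{l_i} λ_{l_k} + ψ_{l_i}[l_i=l_k]) G_{g_i g_k} + σ²e [i=k]`, which
makes REML scores and average-information terms cheap to assemble at the
record level.  Variance parameters are estimated by average-information REML
with step-halving: a candidate step is accepted only if it does not decrease
the restricted log-likelihood, so the accepted trace is monotone.  Variance
components are clamped at zero with a boundary flag rather than allowed
negative.  Convergence requires relative log-likelihood change < 1e−6 and
relative parameter change < 1e−4; because boundary parameters can keep
crawling along a flat ridge on very small problems (e.g. the 9-check model),
three consecutive accepted steps meeting the log-likelihood criterion alone
also declare convergence.  FA1 is sign-indeterminate, so the first nonzero
loading is anchored non-negative.  A phenotype with no residual variation
around the environment means short-circuits to an exact zero-variance fit.

**Prediction.**  Cell (g, e) of the complete GBLUP matrix is
`m̂_e + û_g + λ̂_{l(e)} f̂_g + δ̂_{l(e)g}` where `m̂_e` is the fitted fixed
environment mean; genotypes with no records in an environment (or anywhere)
borrow information through `G` and the loadings.  Values are on the yield
scale because the selection index is a ratio to check performance.

**Checks.**  Reference checks carry no marker data and are fitted in a
separate model of identical form with `G` replaced by the identity.  The
check reference is the per-environment mean of the predicted check yields
within each maturity group; if a line's maturity group has no checks, the
nearest group is used with a logged warning.

## Selection index and classes

    MSI_i = (1/n) Σ_j [ (Y_ij / Check_j) × 100 − 100 ]

averaged by default over *all* environments (observed and predicted cells;
`observed_only=True` restricts to phenotyped cells).  0 means performance
equal to the checks' mean, −5 means 95% of it.  Classes: high (MSI ≥ −5),
moderate (−15 ≤ MSI < −5), low (MSI < −15); the defaults correspond to
roughly 95% and 85% of check performance and are configurable.  The index is
scale-free per environment by construction.

## Classification protocol

Two families: a multinomial elastic-net logistic regression (standardised
features, saga solver; default grid: mixing parameter ∈ {0.1, 0.55, 1.0} ×
10 penalties log-spaced down from the data-derived maximum) and a random
forest (500 trees; candidate features per split ∈ {√m/2, √m, 2√m};
probabilities from vote fractions).  Evaluation uses repeated stratified
hold-out: per outer repetition (default 10) an 80/20 stratified split;
hyperparameters tuned on the 80% alone by inner 5-fold × 5-repeat stratified
CV on overall accuracy (Cohen's kappa available); refit on the full training
subset; out-of-fold predictions pooled across repetitions.  A training split
missing a class is resampled with a log entry.  Equal-probability ties break
deterministically in the fixed class order low < moderate < high.  Class
imbalance is handled by stratification only.

## Evaluation suite

Per-class metrics use the one-vs-rest collapse of the pooled 3×3 confusion
matrix: sensitivity, specificity, precision, NPV, F1, balanced accuracy
((sens+spec)/2), prevalence, detection rate, detection prevalence; zero
denominators surface as NaN with an explicit flag, never 0.  Macro metrics
are unweighted means over the three classes.  Overall: accuracy with a Wald
95% CI (z = 1.96, n = pooled prediction count), Cohen's kappa from the
row/column marginals, the no-information rate (largest class prevalence)
tested by a one-sided exact binomial tail (normal approximation available),
and per-class one-vs-rest McNemar χ² = (b−c)²/(b+c) without continuity
correction (a three-class McNemar is not uniquely defined; all three
collapses are reported, b+c = 0 flagged undefined).

Misclassification severity is the ordinal distance in low < moderate < high:
0 correct, 1 mild, 2 extreme (low↔high confusion).  The decision rule
discards a line when its pooled low-class probability reaches the threshold
(default 0.70, boundary inclusive).  The diversity diagnostic reports
advance/discard centroids and dispersions on PC1–PC2 of the marker PCA and
an overlap coefficient: the fraction of discard points inside the advance
group's 95th-percentile radius (computed inclusively, so identical groups
score ~1); substantial overlap indicates decisions are not explained by
overall genetic similarity alone.

## Synthetic data generator

The generator emulates a two-year early-stage program.  Defaults: 172
bi-parental families × 10 F4:5-derived lines + 9 checks, 2,479 SNPs with MAF
~ U(0.05, 0.5), 2% missing calls, 10 environments (5 locations × 2 years)
with very uneven per-environment observation fractions (0.05–0.58), every
check observed everywhere and every line observed at least once.  Families
are crosses of two simulated inbred parents; lines inherit parental codes
where parents agree and segregate independently per locus elsewhere with
residual heterozygosity 1/16 (F4:5).  No linkage map is simulated (an
optional block-correlation switch exists in spirit through family LD); the
downstream analysis uses no map information.

Genetic effects follow the model above with `f` and `δ` drawn G-correlated
across lines (`interaction_kinship=False` gives iid draws).  Checks carry no
usable marker data downstream; their latent values are drawn independently
of `G` with a mean advantage of 540 kg/ha over the line population and half
the line-scale additive spread — commercial checks are a selected,
genetically narrow elite set.  With μ = 4000 kg/ha, σ²g = 36,000, loadings
100–140, ψ = 8,000 and σ²e = 40,000 (all kg²/ha²), the implied true index
distribution has mean ≈ −11.9 and SD ≈ 7, inducing approximately a 17/50/33%
high/moderate/low split (verified as a three-seed average within ±5 points).
Real trials differ in ways the generator does not capture — linkage
disequilibrium beyond family structure, spatial field trends, maturity ×
environment interactions, non-Gaussian residuals — so passing tests
demonstrate correctness of the machinery under the stated model, not
real-data performance.

Each operation consumes one RNG stream seeded `default_rng([seed, k])`
(k = 0 markers, k = 1 trials, documented draw order), so every output is
byte-reproducible from the config.

## Validation studies (analysis/07, tests)

* **Parameter recovery**: 10 datasets of 300 lines (30 families × 10 sibs),
  300 SNPs, 6 locations × 1 year at 55% observed cells, σ²g = 36,000,
  Λ = (240, −60, 60, 120, 180, 300), Ψ = 15,000, σ²e = 15,000.  Loading
  heterogeneity (including a crossover environment) is deliberate: with
  near-constant loadings ΛΛ′ ≈ λ̄²J is confounded with σ²gJ, and with fewer
  than four locations the cross-location covariances under-determine
  (σ²g, Λ).  Seed-averaged estimates recover each parameter within a few
  percent (the acceptance bound is 25%).
* **Sparse-testing benefit**: masking 20% of observed cells and refitting,
  the model's predictions of the hidden cells correlate with the true
  genetic values at ~0.89 versus ~0.64 for a per-environment means baseline.
* **Signal check**: on 400 lines whose classes are strongly genetically
  determined (σ²g = 60,000 against weak interaction and noise), both model
  families beat the no-information rate at p < 0.01 by the exact binomial
  test; with permuted labels accuracy stays within Monte-Carlo error of it.

Desk-scale problem sizes throughout (hundreds of lines, hundreds of markers,
reduced tuning grids and repetition counts for the studies) are the
package's documented study designs; the full-scale defaults remain available
through `SimConfig()`.

## Numerical and design notes

* GRM requires a PSD matrix within −1e−6 on the smallest eigenvalue; the
  symmetrised product is used.  QC removes monomorphic markers first, so the
  GRM denominator is always positive.
* Imputation visits incomplete columns in increasing-missingness order,
  initialises with per-column modes, and stops when the fraction of imputed
  cells changing between passes reaches `tol` (default 0, i.e. no change) or
  `max_iter` (default 10); 100 trees per column by default.  Observed cells
  are never altered.
* PCA decomposes the column-centered (not standardised) code matrix;
  requested components beyond the rank are dropped with a warning.
* VCF input is parsed with cyvcf2 (biallelic GT); code 2 = homozygous
  reference by default, with a major-allele flip flag.  The GRM is invariant
  to any consistent orientation, and the index/classes never see allele
  orientation.
* Elastic-net penalty grids are derived from the data (λ_max of the pure
  lasso, scaled by the mixing parameter, 10 log-spaced steps down to
  1e−3·λ_max); at extreme penalties predicted probabilities collapse to the
  training class frequencies, which is tested.
* The 298/900/582 class counts and headline accuracies reported for the
  motivating real-data study are not reproducible here — that dataset is
  proprietary and the exact tuning grids and repetition counts are
  unpublished; the package validates the machinery on synthetic data and on
  the analytic identities those reports imply.

## Known limitations

FA order is fixed at 1; no spatial trend correction, multi-trait models,
LD pruning, MAF filtering, map-based imputation, ROC/calibration analysis,
or resampling-based imbalance handling (a stratification-only design is
deliberate).  The AI-REML solver is dense (O(N³) per iteration in the number
of genotype × environment records), comfortable to a few thousand records;
the paper-scale default (~9,000 records) is feasible but slow on one core.
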