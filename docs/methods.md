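# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `biomepred`.

## Study design being emulated

The benchmark reproduces the structure of a commercial grow-finish trial:
offspring of 28 purebred Duroc sires over 6 replicates, each replicate
holding one female and one castrated-male pen of 20 paternal half-sibs per
sire, with 4 animals sampled per pen (28 × 6 × 2 × 4 = 1344 sampled
animals). Fecal 16S profiles are taken at weaning, week 15 and week 22 of
the trial; roughly 1039 of 1344 animals have all three swabs. Twelve
phenotypes are analyzed: four average daily gains (birth→14, weaning→14,
14→22, 14→market) and weight, back fat, loin depth and loin eye area at
weeks 14 and 22.

## OTU preprocessing

* **Abundance filter**: OTUs with total count across all samples below 1200
  are removed. The boundary is inclusive (total = 1200 is retained), reading
  "minimum count to be retained" as an inclusive minimum. The filter is
  applied jointly across all samples by default; per-timepoint filtering is
  available by calling `filter_otus` on each table.
* **Order**: filter first, then rarefy.
* **Rarefaction** to 10,000 reads per sample is multivariate-hypergeometric
  (uniform subsampling of reads without replacement); samples below the
  depth are dropped with a warning. Without-replacement sampling preserves
  expected relative abundances and never inflates a count.
* **W matrix**: the regression design is built from *counts* (not relative
  abundances), centered and scaled per OTU. Scaling statistics are always
  estimated on a declared reference subset — the training fold during
  cross-validation — and applied to all samples, so held-out animals never
  leak into the normalization. Zero-variance columns get scale 1 and a flag.
* **Good's coverage** `1 − singletons/total` is reported per sample as a
  sequencing-completeness diagnostic.

## Jensen-Shannon kernel

For compositions `a, b`, `D(a,b) = sqrt((KL(a‖m) + KL(b‖m))/2)` with
`m = (a+b)/2`, base-2 logarithms and the `0·log 0 = 0` convention. Base 2 is
forced by the requirement that off-diagonal distances range in [0, 1]
(natural logs would cap at √ln2 ≈ 0.83). The similarity `M = 1 − JSD` serves
as the covariance of the per-animal random effect in RKHS regression.
`1 − JSD` is not guaranteed positive semidefinite, so the default repair
clips negative eigenvalues at zero, reconstitutes the matrix and rescales to
a unit diagonal; `repair="none"` reproduces the raw construction and
`"jitter"` adds a diagonal shift instead. The applied eigenvalue floor is
recorded on the `KernelMatrix`.

## Predictor families

All four families fit a *null* form (design factors only: sex, replicate,
sire, weaning-weight covariate) and a *biom* form adding OTU information.
Fixed factors are reference-coded for identifiability; predictions are
invariant to the coding (tested). The sire and weaning-weight terms remain
in the biom models.

**Null / flat Bayesian linear model.** Posterior mean under a flat prior
equals least squares, so the null for the two samplers is an OLS solve;
aliased columns are dropped with a warning.

**Bayesian Lasso.** `y = μ + Xb + Wo + e` with
`o_j | τ_j², σ_e² ~ N(0, τ_j² σ_e²)`, `τ_j² ~ Exp(rate λ²/2)` (so `o_j` is
marginally double-exponential), `σ_e² ~ scaled-inv-χ²(df_e = 5, S_e)` with
`S_e = Var(y)(1 − R2_e)(df_e + 2)` and `R2_e = 0.60`, and flat `b`. The
Gibbs sampler updates `b` in block, `o` coordinate-wise with running
residuals, `1/τ_j²` by inverse-Gaussian draws and `σ_e²` by scaled-inv-χ².
λ is fixed; `select_lambda` performs an internal K-fold grid search on the
training data only (default grid {1, 5, 10, 25, 50, 100, 200}; ties break to
the smaller λ; a full-data search is deliberately not the default, to avoid
leakage). Default λ = 25 sits mid-grid.

**RKHS.** `y = μ + Xb + u + e`, `u ~ N(0, M σ_u²)`. The sampler works in the
eigenbasis of the training kernel (components with eigenvalue ≤ 1e−8 are
dropped), making each sweep O(n²). Prior scales follow
`S = Var(y)·R2·(df+2)` with `R2_u = 0.3`, `R2_e = 0.6`, `df = 5`. Held-out
animals are predicted by the conditional (kriging) mean
`M[test,train] M[train,train]⁻¹ û_train` added to their fixed-effect
predictions; a joint missing-phenotype MCMC would be the alternative and is
left as future work.

**MCMC defaults** are 12,000 iterations, 2,000 burn-in, thinning 5 — chosen
for stable posterior means at the full cohort scale and fully configurable;
the test suite and examples use shorter chains at reduced problem sizes
(stated below). Posterior means are accumulated in streaming form; fits are
deterministic given (data, hyperparameters, seed).

**Tree ensembles** delegate to scikit-learn behind the module surface:
`RandomForestRegressor` (1500 trees, ⌊√p⌋ features per split, squared-error
criterion, unrestricted depth, bootstrap n-out-of-n) and
`GradientBoostingRegressor` (1500 iterations, depth 3, shrinkage 0.01,
squared-error loss, bagging fraction 0.5 per iteration — the fraction is a
package choice, as only "bagging similar to the forest" is specified
upstream). Zero iterations or zero shrinkage degenerate to the training
mean. The timepoint classifier is a random forest with classification
splitting under the same stratified fold scheme, reported as a
row-normalized confusion matrix averaged over folds.

## Cross-validation

"Five-fold" is implemented as 5 repeated sire-stratified random 70/30
splits, not a 5-way partition: a 5-way partition would imply 80/20, which
contradicts the stated ~70%/~30% shares. Within each sire,
`round(0.7·n_sire)` animals are drawn to training per repeat; a
single-offspring sire goes to training with a warning. The same splits are
shared across algorithms and traits for fair comparison. Accuracy is the
mean over repeats of per-repeat Pearson correlations (never
pooled-then-correlated); MSE is recorded alongside. Cells that fail are
recorded as missing, not fatal; constant predictions yield a flagged NaN
accuracy.

**Significance flag**: non-overlap of the null and biom t-based 90% CIs
(4 df at 5 repeats). A Welch t-test alternative is available
(`sig_method="welch"`). The CI-overlap rule is conservative as a two-sided
test (two 90% CIs failing to overlap corresponds to roughly α ≈ 0.01–0.02
for equal-variance cells), but it is two-sided: with pure-noise OTUs, tree
ensembles can be *significantly worse* than their null (noise features
dilute the design factors), and the flag then fires on genuine degradation.
The type-I property of scientific interest — falsely detecting a microbiome
*benefit* — is therefore assessed directionally (biom CI entirely above the
null CI) in the acceptance suite.

**Model averaging** averages per-algorithm mean accuracies
(performance averaging) into `algorithm="AVG"` rows; averaging predictions
instead is a deliberate non-default because the two disagree when
algorithms err in different directions.

## Post-analysis mixed model

The accuracy table (one row per repeat × trait × timepoint × algorithm ×
biom; 1440 rows on a full run) is fitted with all four main effects and all
six pairwise interactions fixed (sum-to-zero contrasts — required for
meaningful Type III sums of squares) and the four-way
Timepoint:Algorithm:Trait:Biom cell as a random intercept. The model
includes the Trait:Biom interaction, giving the 10 fixed terms of the
factorial.

Because the random structure is a grouped intercept, REML is solved by
profiling: `V = σ_e²(I + ρ ZZ')` has a closed-form per-group inverse and
determinant, the profiled criterion is maximized over ρ = σ_g²/σ_e² by
bounded scalar optimization (with an explicit boundary comparison at ρ = 0),
and σ_e² follows in closed form. Type III F statistics are Wald tests of
each term's sum-to-zero coefficients; denominator degrees of freedom are
Satterthwaite, computed per eigencontrast from the gradient of the contrast
variance with respect to (σ_g², σ_e²) and the numerical REML information,
then combined across the contrasts of a multi-df term. On balanced data
this reproduces the exact cell-level residual df (288 − 95 = 193 on the
full factorial) and, with the variance component at zero, matches classical
fixed-effects Type III ANOVA to numerical precision (tested against
statsmodels OLS/anova_lm). LS-means are marginal means over the balanced
factor grid with SEs from the fitted fixed-effect covariance.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Design**: sire × replicate × sex fully crossed, single-sex single-sire
  pens, 4 sampled animals per pen. Weaning weight ~ Normal(5.5, 0.9²) kg
  plus a small per-sire shift (realistic for pigs weaned around 19 days);
  its correlation with early-gain traits arises through its fixed-effect
  coefficient in the trait model.
* **Communities**: Dirichlet-multinomial — per timepoint a baseline
  composition, per sample a Dirichlet(concentration × baseline) draw
  (concentration 50, giving visible overdispersion) and a multinomial at
  the configured depth, so every sample sums exactly to the depth. Six
  dominant OTU blocks (≈55% of OTUs) carry 96.5% of the expected mass,
  mirroring the six phyla that dominate swine fecal communities
  (95.8–97.8% of reads). Timepoint baselines are log-normal perturbations
  of a shared base with standard deviation `separation` (default 0.8);
  separation 0 makes the three timepoints indistinguishable, and the
  default yields near-perfect random-forest timepoint classification, the
  behaviour observed on real cohorts.
* **Traits**: `y = μ + Xb + Wo + e` with `W` the centered/scaled counts of
  the causal timepoint (week 15 by default — the timepoint found most
  predictive in practice; configurable). The realized microbiome signal is
  orthogonalized against the fixed design before rescaling, so the
  requested `microbiome_r2` / `fixed_r2` partition holds exactly up to the
  residual draw. Defaults: `microbiome_r2 = 0.25`, `fixed_r2 = 0.15`,
  dense OTU effects (`n_causal_otus = 0`); published trait means/SDs are
  built in. These defaults put null accuracies near 0.4 and microbiome
  gains near 0.2 at the causal timepoint, the regime reported for
  mid-trial sampling.
* **Dropout**: each animal independently misses one uniformly chosen
  timepoint with probability 1 − 1039/1344 ≈ 0.227, calibrated so the
  complete-case count matches the motivating trial; the true missingness
  mechanism (failed swabs vs sequencing QC) is unknown and modeled
  generically.
* **Determinism**: a single seed fans out to named substreams (design,
  baselines, counts, phenotypes, dropout), so outputs are byte-identical
  for identical (config, seed).

**What the generator does not emulate**: read-level 16S artifacts
(chimeras, taxonomy), pedigree covariances beyond a sire fixed effect,
within-animal longitudinal community dynamics (timepoints are independent
draws), phylogenetic correlation among OTUs, and compositional effects of
true absolute-abundance changes. Passing tests therefore demonstrate that
the estimators recover the signal structure *this* model produces — not
that real swine microbiomes carry that much signal.

## Problem sizes used in the test and acceptance suites

Simulation-backed tests run at reduced scale chosen as the package's own
benchmark conditions: power checks use 28 sires × 4 replicates (n = 896,
matching the "large cohort" regime where all four families are expected to
learn), 120 OTUs at depth 3000, 3 CV repeats, full 1500-tree ensembles and
shortened MCMC chains (2000/500/2); type-I checks use n = 448 with 100
pure-noise OTUs and 5 repeats; structural checks run a miniature full
factorial (64 animals, 30 OTUs) across all 288 cells. GBM requires its full
1500 boosting iterations at shrinkage 0.01 to express its fit; forests and
samplers are insensitive to further scale-up well before that.

## Known limitations

* The RKHS kernel is computed once per timepoint from compositions of all
  samples; this is leakage-free for the kernel *values* (pairwise
  distances do not use phenotypes) but test-animal compositions do enter
  the PSD repair. `repair="none"` avoids even that.
* The CI-overlap significance rule is not a calibrated hypothesis test;
  its directional false-positive rate is checked empirically instead.
* The Bayesian Lasso coordinate sweep is O(np) per iteration in pure
  numpy; at the full 1755-OTU, 12,000-iteration scale a fit takes minutes,
  which is acceptable for the benchmark but not interactive.
* Satterthwaite df relies on a numerical REML information matrix; for
  severely unbalanced accuracy tables (many failed cells) the df are
  approximate.
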