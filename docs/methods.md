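# Methods

`occutrends` estimates long-term regional species-richness trends from
unstructured annual presence records — the kind of data digitized museum
collections and online observation platforms produce. This note describes the
models, the conventions, the synthetic-data generator, and the numerical and
design choices, together with known limitations.

## Data model

Records (one row per specimen/observation, with species, region, year and
taxon) are collapsed to annual detection histories. For a focal taxon, a
region-year is *surveyed* when it holds at least one record of any species of
that taxon; in surveyed years each study species is present (1) or absent (0),
and in unsurveyed years its state is missing. *Recording effort* is the total
record count of the taxon per region-year and is the detection covariate.
Species detected in fewer than two distinct years are dropped (too little
information to separate occupancy dynamics from detection). The survey mask is
per (region, year): a year surveyed in one region may be unsurveyed in
another, because effort is computed per region.

Covariates (annual temperature and forest-cover fraction per region) must be
complete over the modelling span. All design inputs are z-scored over the
span with the population SD; effort is log1p-transformed first because record
counts are heavy-tailed. Transform parameters are stored so any value can be
mapped back.

## Dynamic occupancy model

For one species, occupancy of region r in year t is a latent two-state Markov
chain z_t ∈ {0,1}:

- initial occupancy ψ₁ (fixed at 1 by default; see burn-in below),
- colonization γ_t = logit⁻¹(a₀ + a₁ x_t): probability an unoccupied region
  becomes occupied between t−1 and t,
- extinction ε_t = logit⁻¹(b₀ + b₁ x_t): probability an occupied region
  becomes unoccupied,
- detection p_t = logit⁻¹(c₀ + c₁ e_t) with e_t the standardized log effort;
  no false positives: Pr(y_t = 1 | z_t = 0) = 0.

The dynamics covariate x_t is one of four candidates — constant, linear year,
temperature, forest cover — applied jointly to γ and ε (4 fits per species;
independent γ×ε selection would give 16 and is not the default). The
likelihood is computed by a scaled forward recursion over z (log of the
normalizing constants accumulated per step); unsurveyed years contribute no
emission term. Regions are independent given the parameters.

Maximization uses L-BFGS-B with 5 jittered restarts (intercepts U(−2,2),
slopes U(−1,1) on the logit scale; the first start is the origin), gradient
tolerance 1e−8. Impossible-likelihood boundaries are capped at a large finite
value so finite-difference gradients stay defined. The covariance matrix
comes from the numerically differentiated Hessian at the optimum; a singular
Hessian leaves the fit usable but flags the covariance unavailable. AIC =
2k − 2 logL selects among the four candidates, ties (ΔAIC < 1e−6) breaking
toward fewer parameters, then candidate order.

With a single secondary occasion per year, identifiability of p rests
entirely on the effort covariate and the Markov persistence structure, not on
repeat visits. This is the central approximation of the whole approach and
the reason sparse species' estimates deserve caution.

### Occupancy trajectories and burn-in

Two per-year occurrence probabilities are available: *projected* — the
marginal recursion ψ_t = ψ_{t−1}(1−ε_t) + (1−ψ_{t−1})γ_t, independent of the
data once fitted — and *smoothed* (default) — the posterior
Pr(z_t = 1 | y_{1:T}) by forward–backward. Smoothed estimates feed the
richness analyses; projected ones serve simulation checks and the GOF
statistic. Because ψ₁ is pinned at 1 (there is no information about true
occupancy at the start of a historical series), the first years are burn-in:
the default discards the first 4 modelled years from all downstream analyses,
configurable via `burn_in_years`.

### Goodness of fit

Freeman–Tukey discrepancy Σ (√y − √ŷ)² over surveyed cells, with ŷ the
marginal detection probability (projected occupancy × p). The parametric
bootstrap simulates `n_sim` datasets from the fit on the same survey mask and
reports p = (1 + #{sim ≥ obs}) / (n_sim + 1); species with p < α (default
0.05) are excluded from the primary richness analysis, with an optional
sensitivity rerun keeping them. By default each simulated dataset is
*refitted* (warm-started at the observed optimum) before its statistic is
computed, as in `unmarked::parboot`; the plug-in variant (no refit) is
available but measured severely conservative — with the observed statistic
computed at optimized parameters and the simulated ones at fixed parameters,
p-values compress around 0.5 and the test almost never rejects. Even with
refitting the test remains somewhat conservative: measured type-I error is
≈ 1–3% at α = 0.05 across study sizes, so the GOF screen errs toward keeping
species. The statistic and α are configurable.

## Richness and trend models

Regional species richness is the summed occurrence probability over species
(a plug-in estimator of expected richness), computed only for surveyed,
post-burn-in region-years; unsurveyed years are absent rows, not zeros.
Trait-stratified series sum over one trait class (endemism, habitat
dependence, host-plant specificity); species with unknown values of a trait
are dropped from that trait's analysis only.

Five Gaussian trend models are compared by AIC: intercept-only (SR ~ Region),
linear additive (SR ~ Year + Region), linear interaction (SR ~ Year × Region),
nonlinear additive (SR ~ s(Year) + Region) and nonlinear interaction
(SR ~ s(Year, by Region) + Region). Smooths are penalized cubic regression
splines (B-spline basis, second-order difference penalty) with smoothing
parameters selected by GCV, one penalty per smooth block so by-region curves
get their own amount of smoothing. The basis dimension is chosen once per
suite from the grid {5, 8, 10, 15} (capped at half the unique years) by AIC
and then fixed for all model comparisons. AIC for all forms uses the ML
variance estimate and effective degrees of freedom (trace of the hat matrix;
+1 for the variance), so penalized and ordinary fits are comparable.
Prediction intervals use the Bayesian posterior covariance of the
coefficients — the conventions mgcv users expect. Nested linear-vs-nonlinear
comparisons are reported as approximate F-tests on EDF-based residual df and
should be read as descriptive.

Reporting conventions:

- **Per-decade slope**: annual slope × 10, SE likewise, from the linear
  interaction model via unit-year design contrasts (so the convention is
  identical for additive, interaction and trait models).
- **Direction**: increasing if slope − SE > 0, decreasing if slope + SE < 0,
  stable otherwise (an interval touching zero is stable).
- **Segmentation**: the best smooth fit is predicted on the integer year
  grid; the discrete derivative is the year-to-year difference of predicted
  values (zero differences extend the current run), and maximal runs of
  constant sign become periods. Consecutive periods share their boundary
  year, so period endpoint differences telescope exactly to the total
  predicted change. A period's trend is (ŷ_end − ŷ_start)/(end − start) × 10
  with SE by the delta method from the prediction covariance of the two
  endpoints.
- **Windows**: the linear interaction model is refitted on the trailing 10,
  25, 50, 75, 100, 125, 150 years and the full span; regions with fewer than
  3 observed years in a window, or windows longer than the span, are marked
  unavailable rather than fatal.
- **Trait models**: linear (SR ~ Year×Region + Year×Trait), nonlinear without
  trait, and nonlinear with an added by-trait smooth, compared by AIC. The
  trait-interaction F-test compares the two nonlinear fits with two
  stabilizing conventions: the by-region smooths keep the penalty selected
  under the no-trait model, and the added trait terms are charged their full
  nominal column count (a reference-df convention, in the spirit of
  `summary.gam`'s Ref.df). Raw EDF-based F-tests on freely GCV-selected fits
  rejected a true null ~25% of the time at α = 0.05; the stabilized version
  measured 0/30 null rejections while an opposite-slopes alternative gives
  F in the thousands.

## Synthetic studies

The generator emulates the structure of multi-region historical collection
data with full latent truth: temperature is a linear trend plus Gaussian
noise per region; forest cover a monotone logistic decline; effort a
zero-inflated negative binomial with an optional expedition mixture (a small
probability of a year with several-fold effort), so most region-years carry
no records and a few carry bursts. Defaults — 3 regions, a 170-year span,
~20 species, ~3 expected records per surveyed region-year, 55% structural
zeros — mirror the scale of a museum-collection butterfly study. Latent
chains are simulated per species from the stated dynamics; detection uses the
same standardized-log-effort transform the fitting side applies, so true
detection coefficients live in the estimated parameterization. Per-species
parameters are either given explicitly or drawn from hyper-ranges, with
optional additive year-trend shifts by trait class so trait-stratified
recovery can be tested. One seed drives everything; per-species sub-streams
are spawned deterministically, and a fixed seed reproduces the CSV bundle
byte for byte.

Two emulation notes. A record table implies at least one record per detected
species, so after detections are drawn, a cell's record count is raised to
cover simultaneous detections; detection itself was generated from the
pre-adjustment count (the discrepancy only arises in multi-species cells with
minimal effort, and never in single-species studies). And the generator does
not emulate spatial coordinates, gazetteer noise, taxonomic error or
collector metadata — passing tests say nothing about georeferencing or
identification problems in real data.

## Validation studies and their sizes

`occutrends.validation` holds the replicated studies run by the acceptance
tests and `scripts/acceptance.py`. Sizes were chosen so the full set runs on
one CPU in a few minutes:

- forward-likelihood oracle: 100 random instances with T ≤ 6 against
  exhaustive latent-chain enumeration (agreement ~1e−15 relative);
- parameter recovery: constant dynamics, γ = 0.4, ε = 0.3, effort-linked p,
  50 regions × 60 years, 100 replicates; each probability-scale parameter
  within 3 delta-method SEs of truth;
- covariate selection: forest logit slopes ±2 with a mid-span sigmoidal
  forest decline, 50 regions × 60 years, 200 replicates. When the forest
  curve is near-linear within the span the year candidate is confounded and
  selection splits roughly evenly — a property of the design, not the
  fitter;
- GOF calibration: 500 replicates at 10 regions × 30 years, n_sim = 99;
- end-to-end richness recovery: 12 species, 3 regions, 70 years, default
  effort, all four candidates per species, 50 replicates. Dynamics intercepts
  (γ₀ = −4.0, ε₀ = −4.5 on the logit scale) were grid-searched on the
  analytic marginal recursion so true expected richness declines at
  −0.50/decade before any estimator ran.

## Known limitations

- **GOF conservatism.** The refitting Freeman–Tukey bootstrap under-rejects
  (measured ≈1–3% at nominal 5%). Treat the screen as protection against
  gross misfit, not a calibrated test.
- **Richness-trend attenuation at museum scale.** At a museum-realistic design
  (3 regions, sparse bursty effort), per-species colonization/extinction
  rates are weakly identified, their ML estimates biased toward faster
  dynamics, and the resulting summed-occupancy slope attenuated by roughly
  20% relative to truth; OLS slope SEs on the richness series ignore both the
  occupancy-estimation error and the strong serial dependence of the series,
  so nominal CIs under-cover badly (measured ~10–40% for a 95% CI). The
  estimated series tracks the true richness only moderately cell-by-cell
  (estimate–truth correlation ≈ 0.5 at this design, reported by the
  acceptance script), reflecting how noisy individual region-year estimates
  are at museum-data sparsity. More regions shrink the SE about as
  fast as the bias, so under-coverage persists. Conclusions about trend
  *direction* are more robust than those about magnitude, and interval
  statements on such series should not be taken at face value.
- **Approximate F-tests.** EDF-based df conventions cannot reproduce mgcv's
  internals; all F-tests here are approximate and labelled as such.
- **Single-visit identifiability.** Detection is separated from occupancy
  only through effort and persistence; years with zero effort are treated as
  missing rather than as near-zero detection.
- **Gaussian richness response.** Summed probabilities are continuous and
  bounded; a Gaussian identity-link model is adequate mid-range but can
  produce CI bands crossing the attainable range near 0 or the species count.
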