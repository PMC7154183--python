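# Methods

This note documents the statistical machinery in `quailfcm`, the
choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## The hierarchical random-coefficients model

The response is the FCM concentration of one dropping collection
(pg corticosterone metabolites per mg freeze-dried feces). The study
design is three sequential 48-hour treatments — reference, ACTH
challenge, biological stressor — sampled every 4 hours, giving at most
36 collection windows per bird over 144 hours. Every regression
coefficient is bird-specific and exchangeable across birds:

* likelihood: `Cort_i ~ Normal(x_i' beta_j(i), 1/tau)`;
* random coefficients: `beta_{j,k} ~ Normal(mu_k, 1/tau_k)` for all
  K = 8 effects, including the bird-constant Weight term;
* priors: `mu_k ~ Normal(0, precision 0.001)`,
  `tau, tau_k ~ Gamma(0.1, 0.1)` (shape/rate).

Design coding (`build_design`): Reference is an all-ones intercept;
ACTH and Biological are treatment indicators (reference = both zero);
Time is the window index within a treatment in 4-hour units (0–11);
the interactions are products; Night indicates the 21:00, 01:00 and
05:00 collections (first collection at 09:00); Weight is standardized
to a z-score over the birds present in the table. Two coding choices
deserve comment:

* **Time in window units, not hours.** With window units, an ACTH
  main effect of +12.26 decaying at −1.13 per window returns to the
  reference level after ≈ 10.9 windows ≈ 44 h, matching the
  physiological expectation that an ACTH pulse clears within two days;
  hour-scale coding would imply a 12-fold faster decay.
* **Weight as z-score.** A per-gram coding cannot support an effect
  of order −1 pg/mg over a 73-g weight range without dwarfing every
  other term; the standardized coding makes the Weight coefficient the
  effect of one cohort SD of body mass. Raw grams remain available via
  `build_design(..., weight_scaling="grams")`.

The Night term is carried as a per-bird random coefficient like every
other effect, so "individual variation" has one sigma per effect
(`sigma_k = E[tau_k^{-1/2} | data]`).

## Gibbs sampler

All full conditionals are conjugate; one iteration updates, in order:
per-bird coefficient vectors from their K-variate normal conditional
(precision `tau X_j'X_j + diag(tau_k)`, solved by batched Cholesky
across birds), the population means `mu_k`, the residual precision
`tau ~ Gamma(0.1 + N/2, 0.1 + SSE/2)` and the effect precisions
`tau_k ~ Gamma(0.1 + J/2, 0.1 + S_k/2)`. Defaults are 3 chains of
10 000 iterations with 5 000 burn-in and no thinning. Chains start
overdispersed (chain *c* initializes `mu` at a vague-prior draw scaled
by *c*; precisions at 1), and every chain derives its RNG stream from
`(seed, chain)`, so runs are bitwise reproducible. Point estimates
are posterior means; intervals are empirical type-7 quantiles pooled
across chains after burn-in. Convergence is the classic (non-split)
Gelman–Rubin statistic; the split-chain variant is available via
`rhat(chains, split=True)`. The sampler is cross-checked in the test
suite against a term-by-term log-joint oracle, a closed-form conjugate
posterior with pinned precisions, and a long random-walk Metropolis
run targeting the same log joint.

Degenerate inputs: a sample table with zero weight variance zeroes the
Weight column with a warning rather than dividing by zero; the
per-bird conditional precision is provably nonsingular whenever all
`tau_k > 0`, and a Cholesky failure is reported rather than ridged.

## Synthetic cohort generator

`simulate_fcm` is the exact generative direction of the model above,
with three deliberate departures from a literal Gaussian model:

* **Truncation at zero.** Concentrations cannot be negative, so
  simulated values are clipped at 0. At the default parameter scales
  (reference ≈ 17 pg/mg, residual SD 5) clipping affects well under 1%
  of draws and biases nothing detectably; it is documented here
  because the fitted Gaussian likelihood does not truncate.
* **Missingness.** Whether a bird produces a sample in a window is
  independent Bernoulli(0.70), reproducing the realized ≈ 25 samples
  per bird; we assume missing-completely-at-random, which is also what
  fitting the model to the observed rows assumes.
* **Night term.** Included in generation and fitting alike (the
  diurnal dip is a real feature of the system).

Default truths ship in `src/quailfcm/data/true_params.yaml`: the
population means and per-effect individual-variation SDs of the
validated analysis (reference 16.75 pg/mg, ACTH +12.26 decaying at
−1.13 per window, biological −0.19, night −2.07, weight −1.06; sigmas
3.33, 1.23, 0.64, 0.26, 0.40, 0.26, 0.45, 0.77). The residual SD of a
single 4-hour collection is not published anywhere we can read it off,
so the generator defaults to **5.0 pg/mg**, chosen once as realistic
for droppings whose observed trajectories span roughly 5–45 pg/mg
around treatment means of 14–29 pg/mg; it is configurable.

What the generator does *not* emulate: gut-passage/pharmacokinetic lag
(the ACTH effect switches on at window 0 rather than one window
later), autocorrelated within-bird residuals, assay censoring at the
curve limits, and any age/sex structure beyond balanced class labels.
Consequently, passing recovery tests demonstrates that the estimation
machinery is correct for data matching the model's assumptions — not
that the model is adequate for real bobwhite feces.

## RIA processing and validation

Competitive-assay percent binding is `(count − NSB)/(B0 − NSB)`;
standard curves are ordinary least squares of `logit(B/B0)` on
natural-log dose (the log base cancels in the parallelism F-test and
only rescales the slope; OLS with no heteroscedasticity weighting,
matching simple-regression practice for these curves). Unknowns are
assayed undiluted; back-calculation to pg/mg multiplies the extract
concentration by solvent volume (1 mL) over dry fecal mass (50 mg) —
removing a supernatant aliquot leaves concentration unchanged, and no
extraction-recovery correction is applied.

Parallelism uses the homogeneity-of-slopes F-test: separate-slopes vs
common-slope (separate intercepts) regressions,
`F = [(SSE_c − SSE_s)/(a−1)] / [SSE_s/Σ(n_i−2)]`. The numerator is
computed as `Σ Sxx_i (b_i − b_common)²`, which is exactly zero when
slope estimates coincide; exact fits are detected with a relative
tolerance of 1e-12 on the residual sum of squares, giving F = 0, p = 1
for identical-slope zero-noise fixtures and an explicit degenerate
warning (p = 0) when slopes differ with zero residual variance. The
duplicate-pair intra-assay CV uses the n = 2 sample SD (divisor n−1),
stated here because conventions differ; the inter-assay CV is the
sample CV of one shared control across plates. Both entry points
(pooled duplicates, per-plate controls) are provided since published
CVs do not always say which was used.

`simulate_ria_plates` fabricates plates for these checks: duplicate
B0/NSB tubes, a 5-dose standard series exactly linear in logit–log
space, three serial-dilution series on the first plate whose slope can
be offset to create deliberate non-parallelism, duplicate unknowns and
a shared control, all with multiplicative count noise of configurable
CV. Four lines of five points give the (3, 12) degrees of freedom of
the standard parallelism layout.

## Post hoc peak analysis

Per (bird, treatment) the peak is the maximum observed FCM, ties
broken toward the earliest window. The relationship between ACTH and
biological-stressor peaks is estimated by Bayesian simple linear
regression (vague normal priors, `Gamma(0.1, 0.1)` residual precision,
Gibbs); the posterior mean slope with its 95% credible interval is the
headline number, and a Pearson correlation is reported alongside
because the literature sometimes summarizes this check either way.

## Problem sizes and numerical settings

The standard synthetic-recovery experiment is 23 birds (the analysed
cohort: one juvenile female short of the full 24) × up to 36 windows
at defecation 0.70, ≈ 560–600 observations, fitted with 3 × 10 000
iterations — a few seconds on one core. The calibration study in the
test suite uses 50 replicates at 2 chains × 2 000 iterations, enough
for stable 95% intervals on these conditional posteriors while keeping
the suite fast. Monte-Carlo tolerances in tests are 3 standard errors
(batch-means SEs for correlated draws).

## Known limitations

* Reference and Weight random effects are both constant within a bird,
  so their variance components are only weakly identified: a cohort
  realization can trade `sigma_Reference` against `sigma_Weight`
  (posterior means of roughly 1.7 vs 3.5 pg/mg for `sigma_Reference`
  across seeds). This is accepted as the price of keeping every effect
  a random coefficient; fixing Weight to a population-level effect
  would resolve it at the cost of changing the model.
* With 23 birds, the posterior mean of a treatment effect scatters
  around the generating truth with SD ≈ 1 pg/mg across cohort
  realizations; recovery claims are therefore framed relative to the
  posterior SD (truth within the 95% CrI; posterior mean within 2
  posterior SDs), not as fixed percentages.
* The non-split R-hat can miss certain non-stationary chains that the
  split variant flags; the default mirrors the classic diagnostic, and
  the split form is one flag away.
* No effective-sample-size or model-comparison (DIC/WAIC) machinery is
  provided, and trajectory output is tabular (no plotting).
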