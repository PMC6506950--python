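# Methods notes

## The generative model and its assumptions

`dmbench.simgen` draws OTU tables from a hierarchical Dirichlet-multinomial
with planted covariate effects. The assumptions worth keeping in mind:

- **Composition-level effects.** A spiked association shifts
  `logit(theta_ij)` by `beta_j * x_i` *per entry* and the row is then
  renormalized to the simplex. The entrywise inverse-logit does not preserve
  row sums, and the final multinomial requires a probability vector, so
  renormalization is the only reading that makes the model well defined; it
  also means a spiked OTU perturbs the *relative* abundance of every other
  OTU in the same sample (compositional leakage), which is intended — real
  sequencing data are compositional. With `beta = 0` or `x_i = 0` the
  affected entries are copied through untouched, so the null model
  reproduces `theta` exactly (bit-for-bit, asserted in tests).
- **Between-subject variability** comes solely from the Dirichlet draw; the
  Dirichlet precision (sum of `pi`) controls overdispersion. There is no
  subject-level covariance structure beyond compositionality and no
  confounding between covariate and depth.
- **Depth** is lognormal, rounded to the nearest integer and floored at 1
  (a multinomial size must be a positive integer); whether a real pipeline
  rounds or truncates is immaterial at depths in the thousands.
- **Boundary handling.** Dirichlet draws at tiny `pi` entries underflow to
  exactly 0, where the logit is undefined; entries are clamped to
  `[1e-12, 1 - 1e-12]` before the logit (with a warning) and the row
  renormalized. At depth 2e4 a probability of 1e-12 is indistinguishable
  from 0 in the counts.
- **RNG discipline.** One root seed expands to five independent per-stage
  streams (truth, covariate, baseline, depths, counts), so changing one
  stage's parameters never perturbs another stage's draws; the whole
  pipeline is a pure function of its config.

## Synthetic inputs

- `generate_synthetic_pi(J, concentration=50, tail_shape=2)` draws the
  Dirichlet direction from normalized lognormal weights (log-sd
  `tail_shape`) scaled by `concentration`. Defaults: precision 50
  corresponds to Dirichlet-multinomial overdispersion theta ≈ 0.02, the
  magnitude typically estimated from stool 16S tables; tail_shape 2 puts
  >50% of expected abundance in the top ~10 of 300 OTUs, matching the
  dominance structure of real stool communities. Simulated tables under
  these defaults show the expected realism diagnostics: median per-OTU zero
  fraction ≈ 0.8 at n = 500 / depth 20,000, variance ≫ mean for abundant
  OTUs.
- `generate_dietary_variable(n, skew_target)` uses a sinh-arcsinh-
  transformed standard normal, `sinh((asinh(Z) + eps) / delta)` with the
  tail parameter tied to the skew parameter, `delta = 1/(1 + |eps|/2)`.
  The location parameter alone saturates at population skewness ≈ 1.44;
  coupling the tail weight makes skewness monotone and unbounded in `eps`.
  `eps` is calibrated by Gauss–Hermite quadrature + root finding so the
  *population* skewness equals `skew_target`; draws are then standardized
  to sample mean 0 / sd 1 exactly. An optional zero-inflation mass mimics
  food items many subjects never consume. Sample skewness is everywhere the
  adjusted Fisher–Pearson statistic (`scipy.stats.skew(bias=False)`).
- `fit_dirichlet_multinomial` is the Minka-style digamma fixed point — a
  minorize-maximize scheme, so the log-likelihood trace is non-decreasing
  (asserted); convergence at max parameter change < 1e-8 or 1000
  iterations. Moment-based initialization. All-zero columns are dropped
  (not identifiable). `fit_lognormal` is the plain MLE with n-denominator.

## The four association tests

All methods share the same preprocessing: OTUs with fewer than 10 total
reads or present in fewer than 1% of samples are removed (strict
inequalities, so exact boundaries survive), and `log(total counts)` of the
filtered table is the offset everywhere. p-values are BH-adjusted within
method; "significant" means q < 0.05, strictly.

- **poisson** — Poisson log-linear GLM, two-sided Wald z on the slope. Fit
  by IRLS vectorized across OTUs (the design is the same [1, x] for every
  OTU, so each step is a closed-form 2×2 weighted solve).
- **negbin** — NB2 GLM at fixed per-OTU dispersion, likelihood-ratio test
  against the intercept-only model on chi-square(1). Dispersions come from
  `estimate_dispersions`: Cox–Reid adjusted profile likelihood on a
  log-spaced grid (1e-4…64, 21 points, warm-started IRLS), an
  abundance-dependent trend obtained by lowess-smoothing the profile across
  OTUs at each grid point, and weighted-likelihood shrinkage
  `APL_j + (prior_df / residual df) × APL_trend` with `prior_df = 10`
  (configurable); quadratic interpolation around the grid argmax. OTUs with
  fewer than 3 nonzero observations fall back to the trend value.
- **voom_lm** — log2 cpm with the standard offsets,
  `log2((y + 0.5)/(N + 1) × 1e6)`; per-OTU residual sds from unweighted
  fits; lowess (frac 0.5) of sqrt(sd) against average log2 count;
  observation weights = predicted sqrt-sd at the fitted log-count, to the
  power −4; weighted least squares; residual variances squeezed across OTUs
  by empirical Bayes (hyperparameters by moment matching on log s², the
  trigamma-inverse construction) and a moderated t on d0 + n − 2 df.
- **zig** — per-OTU zero-inflated Gaussian fit by EM: a point mass at zero
  with depth-dependent probability `logit(p_i) = c0 + c1 log N_i`, and a
  Gaussian mean model for the rest. Both M-step subproblems (fractional
  logistic regression, weighted least squares) are solved exactly, so the
  observed-data log-likelihood is non-decreasing (asserted every run).

### Two conventions for the ZIG test

The statistically calibrated version (`zig_association`) models
CSS-normalized `log2(count + 1)` as `b0 + b1 x` and refers the slope to a t
on the *effective* residual df `sum(1 − responsibility) − 2`; its p-values
are approximately uniform under the model's own null (property-tested, KS
< 0.05 at 2000 replicates).

The benchmark path (`run_all_methods`) instead reproduces the operating
characteristics of the zero-inflated Gaussian tool in common use for
marker-gene surveys: raw `log2(count + 1)` with the CSS scaling factor
(`log2(factor/1000 + 1)`) as an extra mean covariate, and the weighted fit
passed to variance moderation with the FULL residual df `n − p`. Zero-heavy
OTUs then divide a small weighted residual sum by a large df, their
variances are underestimated, and the test becomes strongly
anticonservative — which is precisely how that tool behaves in practice and
why it sits where it does in the benchmark rankings. Both conventions share
one EM core; the difference is only in the variance/df bookkeeping.

### CSS normalization

The per-sample factor is the sum of that sample's counts not exceeding its
own `percentile` quantile of *positive* counts (linear-interpolation
quantile); normalized values are `y / factor × 1000`. `"auto"` selects the
percentile by an instability criterion — the smallest percentile at which
the median absolute deviation of per-sample quantiles from the
across-sample reference changes by more than 10% between neighboring
candidates — floored at 0.5.

## Benchmark design

`BenchmarkConfig` defaults define the desk-scale study: 50 simulations of
500 subjects × 300 OTUs at mean depth 20,000 (sigma_L 0.77), spike-ins
Bernoulli(0.5) with t7(0, 2.5) effects, one synthetic composition shared by
all simulations, and one covariate per simulation. These sizes keep a full
benchmark to a few minutes on one CPU while leaving every method hundreds
of tested OTUs per simulation.

The covariate plan assigns each simulation a skewness target. The default
`ffq_like` plan spaces targets as quantiles of an exponential law with mean
1, clipped to [0, 4]: most covariates moderately skewed, a few extreme,
which is the shape of real food-frequency data (and of the 0–4 skewness
span the benchmark is meant to cover). A `uniform` plan (evenly spaced
targets) is available but overweights extreme skewness relative to real
questionnaires and therefore shifts cross-simulation medians upward for
every method. Resampling columns of a user-supplied template matrix with
replacement is supported as the third option.

Scoring: per simulation and method, significant calls are cross-tabulated
against the spike-in truth over the *tested* (filter-surviving) OTUs. The
error probability FP/(TP+FP) is undefined — not zero — when a method calls
nothing, and undefined values are excluded from medians and from
"fraction below 0.05" summaries (counting silence as perfect error control
would reward it). Ties for "lowest error probability in a simulation"
credit no method. The overlap (consensus) set is the four-way intersection
of significant sets, scored the same way.

Per-simulation seeds derive from the root seed by a counter-based scheme
(`SeedSequence([root, sim, stream])`), so results are independent of
execution order and worker count; a rerun with the same config is
bit-identical, and the manifest written alongside the outputs (config +
package versions) suffices to reproduce a run.

## What the synthetic benchmark does and does not show

The simulator reproduces the count-level structure that drives method
disagreement — compositionality, Dirichlet overdispersion, depth variation,
zero inflation, covariate skewness — so it is a fair arbiter of *relative*
operating characteristics. It does not model phylogenetic correlation
between taxa, multiple correlated dietary variables, confounding,
batch/sequencing-run effects, or taxon-specific ecological covariance; a
method's absolute TPR/FPR here should not be read as its field performance.
Absolute rates also depend visibly on scale: with a few hundred OTUs, taxa
are on average more abundant than in a several-thousand-OTU table at the
same total depth, which raises every method's power, lifts the Poisson
false-positive rate toward saturation (nearly every null becomes
rejectable), and narrows the gap between the log-cpm regression and the
negative-binomial GLM. Rankings driven by rare taxa are therefore the
least transferable part of a desk-scale run.

## Numerical choices

- IRLS convergence 1e-10 on coefficients, 50 iterations (12 within the
  dispersion grid, warm-started); linear predictors clipped at ±40 before
  exponentiation; singular 2×2 systems flagged non-estimable rather than
  solved.
- Non-estimable or failed per-OTU fits yield `pvalue = 1, converged =
  False` so result tables stay rectangular; constant covariates are
  rejected the same way.
- EM: responsibilities initialized at 0.5 on zeros followed by an M-step;
  30 iterations or |Δ log-likelihood| < 1e-6; weights floored at 1e-10;
  sigma² floored at 1e-8.
- `squeeze_var` solves the trigamma inverse by Newton; a non-positive
  moment estimate of the prior variance of log s² gives an infinite prior
  df (complete shrinkage), matching the limit behavior asserted in tests.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
  lowess trends to `statsmodels`' implementation.

## Validation against independent oracles

The GLM fitters agree with `statsmodels.GLM` to ~1e-9 on coefficients and
standard errors and beat/match generic Nelder–Mead likelihood maximization
to 1e-6 in log-likelihood; the EM solution is not improved by direct
maximization of the observed-data likelihood; the Dirichlet-multinomial
fixed point recovers known generating parameters and its likelihood trace
is monotone; each method's p-values are uniform under its own generative
null (KS < 0.05 at 2000 replicates). Hand-computed examples pin the BH
step-up, the confusion rates, the CSS factor convention, the log-cpm
offsets and the logit-shift renormalization.
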