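# dmbench

Spike-in simulation and benchmarking of association methods for microbiome
count data.

## The problem

Diet–microbiome association studies regress each taxon's abundance (an OTU
column of a 16S count table) on a continuous dietary covariate, for
thousands of taxa at once. Different count models — Poisson GLM,
negative-binomial GLM, precision-weighted log-cpm regression ("voom +
limma"-style), and the zero-inflated Gaussian mixture used with cumulative
sum scaling — can disagree wildly on the same data, and with real cohorts
there is no ground truth to arbitrate. `dmbench` provides the arbitration
device: a hierarchical Dirichlet-multinomial simulator that generates
realistic OTU tables in which the truly associated taxa are *known*, plus
faithful re-implementations of the four model families and a harness that
scores them against the planted truth.

## The generative model

For `n` subjects and `J` OTUs, with a standardized covariate `x`:

    eta_j   ~ Bernoulli(p)                    which OTUs are truly associated
    gamma_j ~ t_df(0, s)                      raw effect size (logit scale)
    beta_j  = eta_j * gamma_j
    theta_i ~ Dirichlet(pi)                   subject's baseline composition
    logit(mu_ij) = logit(theta_ij) + beta_j * x_i    (rows renormalized)
    N_i     ~ round(Lognormal(mu_L, sigma_L))        library size
    y_i     ~ Multinomial(N_i, mu_i)

Defaults mirror a population-cohort 16S study: `p = 0.5`, `t_7(0, 2.5)`
effects, mean depth 50,000 with `sigma_L = 0.77`. The Dirichlet parameter
`pi` can be fitted to a real table (`fit_dirichlet_multinomial`, a
fixed-point maximum-likelihood Dirichlet-multinomial estimator) or generated
synthetically (`generate_synthetic_pi`) with a heavy-tailed composition —
a few dominant taxa, many rare ones — so the package runs with no external
data. Skew-controllable standardized covariates
(`generate_dietary_variable`) emulate food-frequency-questionnaire items,
whose skewness turns out to drive false positives.

Each simulated dataset is scored per method at BH FDR < 0.05 against the
spike-in truth:

    TPR = TP/(TP+FN)    FPR = FP/(TN+FP)    error probability = FP/(TP+FP)

the last being the realized false-discovery proportion among that
simulation's significant calls.

## Worked example

```
$ dmbench simulate --n-subjects 500 --n-otus 300 --mean-depth 20000 \
      --skew 1.0 --seed 42 --out ds
$ dmbench run-methods --dataset ds --out results.tsv
$ dmbench evaluate --results results.tsv --truth ds/truth.tsv
 method  tp  fp  tn  fn      tpr      fpr  error_probability
 negbin  84   8 115  68 0.552632 0.065041           0.086957
poisson 150 107  16   2 0.986842 0.869919           0.416342
voom_lm  96   8 115  56 0.631579 0.065041           0.076923
    zig 136  52  71  16 0.894737 0.422764           0.276596
```

Reading the table: of the 275 OTUs that pass the abundance filter, the
Poisson GLM recovers almost every truly associated taxon (TPR 0.99) but also
calls 87% of the null taxa significant — overdispersed counts make its Wald
tests wildly anticonservative, so 42% of its "discoveries" are false. The
negative-binomial GLM with empirical-Bayes dispersions is the most
conservative (TPR 0.55) but keeps the realized false-discovery proportion
near 9%. The zero-inflated Gaussian sits in between on power but inherits
the anticonservative variance convention of its reference implementation
(28% of calls false), and the precision-weighted log-cpm regression gives
the best error control here.

The same comparison across many simulations, with a skewness-varying
covariate plan, consensus ("overlap") sets and summary rankings:

```python
from dmbench import BenchmarkConfig, run_benchmark

summary = run_benchmark(BenchmarkConfig(n_simulations=50, seed=1))
print(summary.medians)           # per-method median TPR/FPR/error probability
print(summary.overlap_frac_below)  # fraction of sims with overlap error < 0.05
```

or `dmbench benchmark --n-simulations 50 --seed 1 --outdir bench/` followed
by `dmbench report --per-sim bench/per_simulation.tsv --outdir figs/`.

## Layout

- `dmbench.simgen` — the generative model
- `dmbench.fixtures` — composition/depth estimators and synthetic inputs
- `dmbench.preprocess` — OTU filtering, log-cpm, cumulative sum scaling
- `dmbench.glm`, `dmbench.voom`, `dmbench.zig` — the four association tests
- `dmbench.assoc` — run all methods on one dataset
- `dmbench.evaluate` — confusion counts, rates, consensus sets, summaries
- `dmbench.benchmark`, `dmbench.cli`, `dmbench.io`, `dmbench.plots` —
  orchestration, command line, serialization, figures

See `docs/methods.md` for the modeling decisions, parameter defaults and
known limitations.
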