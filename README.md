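# dpcollab

Collaborative statistical analysis from **differentially private synthetic
data**, for multi-center health studies where raw records cannot leave a site.

Several parties (study centers) each hold a small, locally skewed tabular
data set — categorical ethnic/socioeconomic-style features plus a binary
test-result outcome — and all want to fit the same downstream model well *on
the population level*. Pooling records is precluded by privacy. Instead, each
party:

1. fits a generative model to its local data with **differentially private
   variational inference** (DPVI: DP-SGD on a reparameterized ELBO —
   per-example gradient clipping, Gaussian noise, Poisson subsampling — with
   a numerical privacy-loss-distribution accountant for the total (ε, δ));
2. draws **K parameter vectors** from the fitted posterior and publishes one
   synthetic data replicate per draw;
3. combines its own records with the k-th replicate from every *other* party,
   fits the downstream model K times, and merges the fits with **Rubin's
   rules** (mean w̄ = mean_k(w_k); variance v̂ = (1+1/K)b − v̄ with
   between-replicate variance b and mean within-variance v̄, falling back per
   coefficient to (1+1/K)b + v̄ where negative).

The downstream model is a Poisson regression with log link,
λ = exp(wᵀx̃), predicting y ∈ {0,1} by the pmf argmax (1 iff λ > 1); the
generative model is a 16-component mixture of product-categoricals over the
features with the same regression as outcome part. Utility is the predictive
log-likelihood Σ(y ln λ − λ − ln y!) on a global held-out test set, and its
Monte-Carlo sampling distribution under w ~ N(w̄, diag(v̂)); sample sets are
compared with Welch's t-test on pooled mid-ranks.

Because no real multi-center cohort can ship with the package, a first-class
`cohort` module simulates one with known ground truth (8 heterogeneous
centers, rare outcome, a minority subgroup, a tunable center-distribution
tilt and a two-way-marginal skew knob), so every stage of the protocol is
testable end to end.

## Worked example

Eight simulated centers, ~200 local training records each after the 10%
subsample, privacy target (ε, δ) = (1, 10⁻⁶) per center, K = 20 synthetic
replicates, 3 protocol repeats:

```python
from dpcollab import ExperimentConfig, run_combined_vs_local, summarize_significance

cfg = ExperimentConfig(seed=1, k_replicates=20, n_repeats=3, n_permutations=3)
table = run_combined_vs_local(cfg)

per_center = table[table.center >= 0]
means = per_center.groupby(["center", "condition"]).loglik.mean().unstack()
sig = summarize_significance(per_center, "combined", "local", sides="one")
print(means.round(3))
print("pooled-data baseline mean:",
      round(table[table.condition == "pooled"].loglik.mean(), 3))
```

which prints (normalized predictive log-likelihoods on the global test set):

```
condition  combined          local
center
0            -0.454 -6.704170e+128
1            -0.458  -5.870000e-01
2            -0.458 -7.881663e+128
3            -0.457 -4.273144e+128
4            -0.460  -5.080000e-01
5            -0.457 -1.211565e+129
6            -0.459 -2.235586e+128
7            -0.453 -6.643985e+128
pooled-data baseline mean: -0.434
```

Reading this: models fitted on ~200 local records are so unstable that
Monte-Carlo draws from their parameter distribution occasionally produce
astronomically bad predictions (the e+128 means — a handful of centers keep
finite but poor values like −0.59). Combining local data with the other
seven centers' DP synthetic releases stabilizes every center near −0.45,
close to the privacy-agnostic pool-everything baseline (−0.434) that the
protocol is designed to approximate without sharing records. The one-sided
ranked-Welch p-values for combined > local are below 10⁻⁵⁰ for all eight
centers.

A command-line interface mirrors the pipeline (`dpcollab simulate`,
`fit-generator`, `release`, `analyze`, `experiment
{combined,incremental,size-sweep,skew}`, `summarize`); run
`dpcollab --help`.

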