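# Methods

`dpcollab` implements and evaluates a collaboration protocol for parties
(study centers) that each hold a sensitive tabular data set and want to
improve a shared downstream analysis without ever exchanging raw records:
every party fits a differentially private generative model locally, publishes
synthetic data sampled from it, and every party re-runs the analysis on its
own data augmented with everyone else's synthetic releases.

## The models

**Analysis model.** The downstream task is a Poisson regression with log link
predicting a binary test result *y* from *d* categorical features *x*:

    f(x; w) = argmax_{y in {0,1}}  λ^y e^{-λ} / y!,    λ = exp(wᵀ x̃),

where x̃ is the dummy-encoded feature vector (leading intercept, one indicator
per non-reference level; full one-hot would make the MLE non-identifiable next
to the intercept). The argmax over {0,1} reduces to `1 iff λ > 1`, with the
tie at λ = 1 resolved to 0. Poisson regression on a binary outcome is the
standard epidemiological choice when risk ratios rather than odds ratios are
wanted; for the rare outcomes simulated here (~13% positive) the clipping of
Poisson counts to {0,1} changes the likelihood only slightly.

**Generative model.** Each party's synthetic-data generator has two parts: a
mixture of product-categoricals over the features,

    p(x | θ, π) = Σ_{r=1..R} π_r Π_{j=1..d} Cat(x_j | θ_j^(r)),   R = 16,

and an outcome part that exactly mirrors the analysis regression,
`y ~ Poisson(exp(wᵀ x̃))`, clipped to `min(y, 1)` so sampled cohorts keep the
binary schema. Population generation and synthetic-data sampling share one
code path for this outcome mapping.

## Differentially private inference

The generative model is fitted by variational inference with a mean-field
Gaussian posterior over an unconstrained parameterization: stick-breaking
bijections for the mixture simplex and each component categorical, identity
for the regression weights. Priors are uniform (Dirichlet(1)) on every simplex
and N(0, 2²) on each regression weight — weakly informative, recorded in
`transforms.py`.

Training is DP stochastic gradient ascent on a single-sample reparameterized
ELBO: each iteration Poisson-subsamples the data at rate *q*, computes
analytic per-example gradients (each example's contribution is its
log-likelihood gradient plus 1/n of the prior-minus-entropy gradient), clips
every per-example gradient to L2 norm *C*, sums, adds isotropic Gaussian
noise of scale σC, divides by the expected batch size *qn*, and applies an
Adam step. The clipped-and-noised sum is the only data-dependent quantity the
optimizer ever sees; an interface test asserts this boundary.

**Accounting.** Total privacy over *T* iterations is computed with a
numerical privacy-loss-distribution accountant for the Poisson-subsampled
Gaussian mechanism under the add-remove neighbourhood: the single-step
privacy-loss density is discretized on a fine grid (2^18 loss bins fed from
2^20 quadrature points), composed *T*-fold by FFT, and δ(ε) read off for both
adjacency directions, the worse being reported; ε(δ) follows by bisection. At
q = 1, T = 1 the result matches the exact analytic Gaussian-mechanism curve
to ~3·10⁻⁶ relative. An independent Rényi-DP composition bound (the standard
sampled-Gaussian integer-order formula) serves as a cross-check: the PLD
result must never exceed it, and the test suite enforces this on a parameter
grid. `calibrate_noise` inverts the accountant by bisection, returning the
smallest σ whose realized ε lies in (0.999·target, target].

**DP-SGD defaults.** The privacy regime fixes (ε, δ) = (1, 10⁻⁶) per fit.
The remaining knobs are the package's own, chosen once from pilot
parameter-recovery runs at the default problem size (n ≈ 200 records,
R = 16, d = 5): expected batch size qn ≈ 25, T = 8000 iterations, clip norm
C = 2, Adam step size 0.02. Smaller batches with more iterations spend the
same privacy budget at lower per-step noise relative to the batch signal,
which proved decisive for learning the feature marginals; the moderate clip
norm keeps the (rare) positive-outcome gradients from being crushed, which
would otherwise bias the learned outcome rate downward. All of these are
`ExperimentConfig`/`OptimizerConfig` fields and can be overridden; the
realized ε of every fit is logged in the release manifest.

## Release and combination

Each party draws K parameter vectors from its posterior and samples one
synthetic replicate per draw, of the same size as its training data (K = 100
in the reference protocol; the scaled study runs use K = 20). A recipient
forms K combined training sets — its own records plus replicate k from every
*other* party (records carry internal provenance tags so the
own-data-exclusion is assertable; tags never reach exported CSV). The K
downstream fits (w_k, v_k) are merged with the fully-synthetic-data variant
of Rubin's rules:

    w̄ = mean_k w_k,   b = Var_k(w_k) (divisor K−1),   v̄ = mean_k v_k,
    v̂ = (1 + 1/K) b − v̄,  replaced per coefficient by (1 + 1/K) b + v̄
    wherever the first form is negative.

The rules are applied element-wise per coefficient — the only reading that
yields a valid diagonal covariance.

Utility is the predictive log-likelihood Σ (y ln λ − λ − ln y!) on a global
test set (the union of per-center 20% holdouts), normalized by the test size.
Its sampling distribution comes from 100 Monte-Carlo draws of w from
N(w̄, diag(v̂)); for local-only baselines the single fit's (ŵ, v̂) plays the
same role. Differences between log-likelihood sample sets are tested with
Welch's t on pooled mid-ranks (robust to unequal variance and non-normal
samples), one-sided for "sharing helps" comparisons and two-sided for the
skew comparisons.

## The simulated cohort

No real multi-center cohort ships with the package; the `cohort` module
generates one with known ground truth, emulating a voluntary-enrolment
health study:

- d = 5 categorical features with level counts (5, 4, 3, 3, 2), echoing
  ethnic/socioeconomic survey factors; the first feature carries a ~7%
  minority category that the skew experiment targets;
- truth is a 4-component mixture whose component categoricals are
  Dirichlet(30·base) perturbations of fixed base marginals — real latent
  structure at mild strength;
- outcome weights have intercept −2 (base positive rate ≈ 13%, a plausible
  test-positivity rate) and effects up to 0.8 on the minority category;
- 20 000 records split over M = 8 centers. Center assignment draws per-center
  log-affinities over the first feature's categories from N(0, tilt²)
  (default tilt = 1) and balances them Sinkhorn-style against the empirical
  category distribution, so every center's expected size is n/M while its
  composition — hence its local distribution — shifts away from the
  population (Pr[x|m] ≠ Pr[x]). The tilt is a one-knob stand-in for real
  center heterogeneity, not a calibration to any particular study.
- per-center 80/20 train/test split, training data subsampled to 10% for the
  main experiments → ~200 records per center.

What the generator deliberately does not model: continuous or ordinal
features, missingness, correlated center sizes, temporal drift, or any
real cohort's geography. Passing tests therefore demonstrate that the
*protocol machinery* behaves as designed under realistic smallness, rarity
and heterogeneity — not that any particular real data set would show the
same effect sizes.

## Experiment designs and scaled conditions

The reference protocol uses K = 100, 100 log-likelihood samples, 10 repeats
and 100 sharing orders. The default acceptance-scale runs (test suite and
`scripts/acceptance.py`) use K = 20, 3 repeats and 3 orders at the same
cohort size and privacy target — sizes chosen so a complete run takes minutes
on one CPU while leaving the qualitative findings intact:

- **combined vs local** — every center's local-only model against its
  Rubin-combined model using all other centers' releases, plus the
  privacy-agnostic pooled-data baseline;
- **incremental** — other centers' releases added one at a time
  (replicate-aligned, so K stays fixed at every step) in random orders;
- **size sweep** — the combined-vs-local design at training fractions
  {10, 20, 50, 100}%;
- **skew** — an artificial population-matched party built from half the
  global test set; its (minority category, positive outcome) two-way cell is
  depleted to keep fractions {10, 25, 50, 75}% (rounding half-up so small
  cells survive); evaluation is restricted to the minority subgroup of the
  other, disjoint test half.

Repeats reseed inference, release and log-likelihood sampling; the cohort and
its split are fixed across repeats (so repeats measure protocol randomness,
not cohort randomness). All randomness fans out from one master seed through
named streams; every result table is bit-reproducible from (config, seed).

## Numerical choices and degenerate inputs

- Mixture likelihoods are evaluated in log space with max-shifted summation;
  probabilities are floored at 1e-300 before logs.
- The linear predictor is capped (at 30 during training, at 300 during
  evaluation) so pathological parameter draws yield very poor but finite
  log-likelihoods instead of overflowing.
- The downstream fit drops dummy columns whose level is unobserved in the
  training data and zero-fills them in the returned vectors; genuinely
  collinear observed columns raise an error naming them. Coefficient
  variances come from the Fisher information evaluated exactly at the
  returned MLE (the IRLS covariance reflects the penultimate iteration).
- Separation — a level with no positive outcomes, common at n ≈ 200 with a
  13% outcome — flags the fit as non-converged. Rubin combination uses
  converged fits; when fewer than two combined-set fits converge (typical at
  the first incremental step), all finite fits are combined instead, letting
  the extreme coefficients show up honestly as a wild log-likelihood spread.
- Subsampling rounds down; skew-cell depletion rounds half-up; the 80/20
  split gives each center floor(0.8·n) training records.
- All-tied inputs to the ranked Welch test return p = 1 by convention.

## Known limitations

- At ε = 1 on ~200 records the fitted generative model captures coarse
  marginals and the outcome base rate but little conditional structure; the
  collaboration benefit at this scale comes mostly from variance reduction
  and de-biasing toward the population, which is exactly the regime the
  protocol targets, but absolute synthetic-data fidelity is low.
- The accountant's FFT composition is numerically accurate rather than
  formally conservative (no discretization-error certificates); the RDP
  cross-check bounds gross error.
- Rubin intervals use the Gaussian approximation throughout; no
  Barnard–Rubin degrees-of-freedom correction.
- Parties are honest; transport, licensing and malicious-release robustness
  are out of scope.
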