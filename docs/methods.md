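# Methods

## The model

Whole-genome regression for genomic-enabled prediction fits

    y = X beta + eps,        eps ~ N(0, I_n sigma2_e),

with `y` the centred phenotypes of `n` lines and `X` the n×p marker matrix
(0/1/2 SNP dosages or 0/1 dominant calls). With p ≫ n and strong linkage
disequilibrium, `X` is rank-deficient or severely ill-conditioned, so the
least-squares problem is treated as a discrete inverse problem. Writing the
SVD as X = U S V′ and rotating both sides by U′ gives the reduced model

    d_i = s_i b_i + e_i,     i = 1..r,      d = U′y,  b = V′beta,

where r = rank(X) and the likelihood factorises over coefficients. Only the
first r entries of `b` are identified; the remaining p−r directions get a
point-mass-at-zero prior and the marker effects are recovered as
beta = V1 b. The OLS solution b*_i = d_i/s_i has variance proportional to
1/s_i², so trailing (small-s) coefficients are noise-amplified — the
motivation for priors whose variance decays along the spectrum.

Each coefficient gets a conditionally Gaussian prior b_i ~ N(0, lam_i), and
the four models differ only in lam:

| model | lam_i                         | interpretation |
|-------|-------------------------------|----------------|
| BIRR  | sigma2_b                      | flat prior variance; spectral analogue of Bayesian ridge regression |
| BAI   | sigma2_b_i                    | per-coefficient variances (scaled-t marginal); Bayes A analogue |
| BIR1  | phi · (i^(−1−2·alpha) + h)    | polynomial index decay, smoothed by h |
| BIR2  | phi · s_i^alpha               | decay tied to the singular values |

The conditional posterior mean of b_i is f_i · b*_i with the weighting
factor f_i = lam_i s_i² / (lam_i s_i² + sigma2_e) ∈ (0, 1): components with
strong signal are left nearly untouched, noise-dominated tail components
are shrunk towards zero. With constant lam the posterior mean reproduces
the ridge estimator b_i = s_i d_i / (s_i² + gamma) with
gamma = sigma2_e / sigma2_b, which is the identity the test suite checks
against a dense (X′X + κI)⁻¹X′y solve.

## Priors and defaults

All variance parameters carry scaled-inverse-chi-square priors in the
convention density ∝ x^(−df/2−1) exp(−df·Sc/(2x)) (mean df·Sc/(df−2)); this
is stated explicitly because two parameterizations circulate. Scale
hyperparameters (Sc_b, Sc_phi) get uniform (0, A) hyperpriors, giving a
truncated-Gamma full conditional.

Defaults, applied only to fields the user leaves unset:

* df_b = df_phi = df_e = 3 — weakly informative, and df_b = 0 would make
  the coefficient prior improper.
* Sc_e = var(d)/2 — anchors the error-prior scale at half the phenotypic
  variance, so the prior is centred on an even signal/noise split.
* A = max(10·var(d)·median(1/g_i), 10·var(d)) — roomy enough that the
  uniform bound is rarely active, covariant under rescaling of y.
* alpha = 1 for BIR2 (its default decay); alpha = 0.5 for BIR1, the
  midpoint of the i^(−1) … i^(−3) decay family over alpha ∈ [0, 1]. BIR1's
  alpha has no canonical value; it is exposed as a parameter.
* h = 1/s1 for BIR1 — the reciprocal of the leading singular value, giving
  the tail of the prior-variance profile a floor so late coefficients are
  not annihilated (≈ 0.1 for marker matrices whose leading singular value
  is near 10).

Doubling y quadruples var(d) and hence Sc_e and A proportionally, so the
defaults are scale-covariant (tested).

Phenotypes are centred by the training mean by default (the model carries
no intercept); marker codes are used as provided. Matrices with missing
genotype calls are rejected rather than silently imputed.

## Gibbs sampler

All full conditionals are closed-form by Normal/scaled-inverse-chi-square
conjugacy (they are listed in `invgp.gibbs`'s module docstring). One sweep
updates, in fixed order: coefficients b (vectorised, jointly independent) →
sigma2_e → coefficient variances → hyper-scale. The order is arbitrary
asymptotically and fixed for reproducibility. Default chain: 60,000
iterations, 10,000 burn-in, thinning 10 → 5,000 retained draws.

Numerical choices:

* Truncated-Gamma draws use the inverse-CDF via `scipy.special.gammaincinv`;
  when the Gamma CDF underflows at the bound, the kernel on (0, A) is the
  pure power x^(shape−1) and its analytic inverse CDF is used instead. A
  degenerate zero rate falls back to Uniform(0, A). Draws are clipped into
  the open interval by a relative 1e−12 margin.
* Rank truncation drops singular values below trunc_tol·s1 (default
  1e−10) — exact-rank behaviour on clean data while removing near-zero
  singular values that would otherwise explode the OLS tail.
* SVD signs are fixed so the largest-magnitude entry of each V1 column is
  positive; predictions are invariant, output is deterministic.
* Tied singular values: the decomposition's stable order is kept; all
  quantities consumed downstream (fits, predictions) are rotation-invariant
  within a tied subspace.
* Initialization: b at the OLS solution (non-finite entries zeroed),
  sigma2_e = var(d)/2, coefficient variance var(d)/2 scaled by the mean of
  the decay profile, Sc at A/2 — overdispersed but scale-matched.
* One `SeedSequence` per chain spawns four independent substreams (one per
  update block), so chains are bit-reproducible given (seed, data, spec)
  and structurally identical models consume identical randomness. This is
  why BIR2 with alpha = 0 (flat profile) reproduces BIRR draw-for-draw on
  the same seed — the intended limiting identity, here exact.

## Cross-validation

Predictive ability is scored over repeated random partitions (default 50)
with 90% training / 10% testing, by Pearson correlation between predicted
and observed phenotypes and predictive mean squared error (PMSE), plus
pairwise win counts (ties counted for neither side). Everything
fold-dependent — y centring, the SVD basis, hyperparameter defaults — is
recomputed from training rows only; a leakage test perturbs held-out
phenotypes and asserts the fit is unchanged. Whether the original analyses
re-decomposed per fold is unknowable from the outside; per-fold
recomputation is the defensible choice and is what this package does.
Test-set size is round(fraction·n), minimum 1. Chain seeds derive from
(cv seed, partition index, model slot), so single-model runs are
reproducible independently of which other models run alongside.

## Synthetic data

The generator emulates the breeding-panel regime the models target: n in
the hundreds, p ≫ n, LD blocks, moderate-to-strong singular-value decay.
Defaults (chosen once): n = 300, p = 1,000, MAF ~ Uniform(0.05, 0.5), LD
blocks of 20 markers with latent-factor loading 0.7, fully polygenic
Gaussian effects, h² = 0.5. Markers are produced by thresholding, per
gamete, a shared block factor plus idiosyncratic noise at Phi⁻¹(q_j), so
marginal allele frequencies are exact while within-block correlation — and
the spectral decay — is controlled by the loading. Residuals are centred,
projected orthogonal to the genetic values and rescaled, making realized
Var(u)/Var(y) equal h² as an identity.

What the generator does not emulate: recombination maps, mutation,
population structure/relatedness, dominance/epistasis, non-Gaussian trait
noise, genotyping error. Passing tests therefore demonstrate correctness of
the machinery and calibrated behaviour under the assumed additive model,
not performance on any real population.

Problem sizes used in the validation harness (the package's own choice of
desk-scale defaults): recovery experiments at n = 300, p = 1,000 with
20,000-iteration chains; structural-identity and null-trait checks at
n = 150–300 with shorter chains; the four-model comparison at 15 partitions.
At these sizes a full run of the validation script completes in about a
minute on one core.

## Known limitations

* The held-out predictive correlation of a single 10% split (30 lines) is a
  noisy statistic: per-dataset standard deviation ≈ 0.18 at h² = 0.5 under
  the default generator. Conclusions about model ranking need the full
  repeated-partition machinery, not single splits.
* sigma2_e and sigma2_b are separately identified only when the spectrum
  contains both signal-dominated and noise-dominated components; on
  near-flat spectra the two trade off and posterior means inherit that
  ridge (the sampler agrees with a grid-evaluated marginal posterior in
  such cases — the flatness is in the posterior, not the algorithm).
* BAI's per-coefficient variances make its Sc_b conditional depend on all r
  variances; its mixing is slower than the scalar-variance models at equal
  chain length.
* No multiple-chain diagnostics (Gelman–Rubin etc.); single-chain trace
  summaries only.
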