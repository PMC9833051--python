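# Methods

## The observer model

The package models a perceptual observer in a linear ("sensory-space") stimulus
domain. On each exposure to a stimulus x the observer draws an internal
measurement m from N(x, σ²) — unbiased, additive, homoscedastic Gaussian noise.
Stimulus domains that obey Weber–Fechner scaling should be log-transformed by
the user before fitting; the package deliberately does not apply any transform.
Circular domains (orientation, direction) are out of scope, as are
non-Gaussian or stimulus-dependent likelihoods.

The prior is a mixture of C Gaussians with weights wᵢ, means νᵢ, SDs γᵢ.
Because the Gaussian family is closed under products, the posterior is again a
mixture whose components have shrinkage αᵢ = γᵢ²/(γᵢ²+σ²), offset
ν̃ᵢ = (1−αᵢ)νᵢ, and variance αᵢσ². The posterior weights
w̃ᵢ(m) ∝ wᵢ N(m; νᵢ, γᵢ²+σ²) are computed in log space with log-sum-exp;
measurements many prior SDs from every component would otherwise underflow the
raw densities. If every component underflows even in log space the code raises
rather than returning a normalized vector of garbage.

Two loss functions are supported for point estimation: squared error, giving
the Bayesian least-squares (BLS) estimate = posterior mean, analytic for any
mixture; and zero-one, giving the MAP estimate = posterior mode, found by a
4001-point scan plus bounded refinement. For a Gaussian posterior the two
coincide. Exact ties between modes return the smallest maximizer and emit a
warning, so bimodal posteriors never make the estimator nondeterministic.

## Estimate distributions

Repeated presentations of x generate an estimate distribution p(x̂|x). Three
routes are implemented:

* **exact_sg** (C = 1): N(αx + ν̃, α²σ²).
* **numeric** (any C): tabulate T(m) = BLS(m) on a measurement grid, invert by
  piecewise-linear interpolation, and apply the change of variables
  p(x̂|x) = N(T⁻¹(x̂); x, σ²)·|dT⁻¹/dx̂|, the derivative taken by finite
  differences on the table. The BLS map is strictly increasing for every
  mixture prior (dT/dm = Var(x|m)/σ² > 0), so this route is always available
  for BLS; the monotonicity flag exists to guard MAP tables and degenerate
  numerics, and non-monotone tables are refused rather than pseudo-inverted.
* **approx** (any C): freeze the posterior weights at the expected measurement,
  w̃ᵢ(x) ≈ w̃ᵢ(m). T becomes affine and p(x̂|x) Gaussian with mean
  Σᵢw̃ᵢ(x)(αᵢx+ν̃ᵢ) and SD σ·Σᵢw̃ᵢ(x)αᵢ. The frozen-weight inverse uses the
  posterior offsets ν̃ᵢ in the numerator, consistent with the forward map; a
  `literal_offsets` switch substitutes the raw component means νᵢ for
  comparison with an alternative printed form of the same expression.

### Grid conventions

All gridded densities use a uniform grid centered on the mixture mean spanning
±8·max(maxᵢ(γᵢ+|νᵢ|), σ) with 2001 points. For likelihood evaluation the span
is extended (at fixed spacing, capped at 8001 points) to cover the observed
stimuli ±4σ. Keeping the default *spacing* rather than the default point count
matters: stretching a fixed-size grid over a degenerate parameter proposal
(huge σ, tiny γ) smears sharp features of T across whole cells and misprices
the change-of-variables density — early versions of the fitter exploited
exactly that to reach spurious likelihood maxima. Estimates outside the range
tabulated by T contribute a floored log density of log(1e-12) and are counted
in the log, never silently dropped.

## 2AFC psychometrics

The observer compares two stimuli measured with noise σ₁, σ₂ under a shared
prior and answers "yes" (stimulus 2 larger) when P(x₂ > x₁ | m₁, m₂) > ½, with
ties counted as "no" (a measure-zero set; the strict inequality keeps the rule
deterministic). The exceedance probability has a closed form as a double sum of
normal CDFs over posterior component pairs.

p("yes"|x₁,x₂) is computed three ways:

* **sg_analytic** (C = 1): the cumulative normal
  Φ((α₂x₂+ν̃₂−α₁x₁−ν̃₁)/√(α₁²σ₁²+α₂²σ₂²)). The offset difference ν̃₂−ν̃₁ is
  kept so the expression is exact for non-zero-mean priors.
* **numeric** (any C): the exceedance is evaluated in closed form at every node
  of an 801×801 measurement grid spanning each stimulus ±6σ; the 0.5-level
  crossings along m₂ are located by linear interpolation within each m₁ row;
  the inner m₂ integral over the "yes" region is then exact (Gaussian CDFs over
  the decision intervals) and the outer m₁ integral is a trapezoid over a
  smooth integrand. Compared with integrating the binary decision indicator
  directly, this removes the O(h) boundary-discretization error; the numeric
  and analytic routes then agree to ~10⁻⁹ for single-Gaussian observers, and
  doubling the grid moves results by <10⁻⁶ (a convergence check asserted
  before benchmark runs, threshold 5·10⁻⁴). Rows whose decision profile is not
  a single upward crossing (possible for bimodal priors) fall back to an
  explicit interval decomposition. The row structure depends only on the
  observer, so one decision table serves a whole sweep of stimulus values.
* **mog_approx** (any C): weights frozen at w̃ᵢ(x₁), w̃ⱼ(x₂); both estimate
  distributions become Gaussian and p("yes") is again a cumulative normal.
  For C = 1 this reduces to sg_analytic at machine precision.

The PSE is found by bisection of p("yes")−½ in x₂ (tolerance 10⁻⁶ stimulus
units). The slope at the PSE is reported as the standard sensitivity metric
1/(σ_diff√(2π)) for the cumulative-normal routes — the slope per unit of the
estimate-difference mean; the numeric route reports a central-difference slope
per unit x₂, which differs by the effective shrinkage of stimulus 2. The
perceptual bias is the unsquared ratio of effective shrinkage sums
(Σᵢw̃ᵢ(x₁)αᵢ)/(Σⱼw̃ⱼ(x₂)αⱼ) — the form that reduces to α₁/α₂ for C = 1 and
whose analytic extremes reproduce the benchmark range below; a `squared`
switch exposes the squared variant for comparison.

## Fitting

Negative log-likelihoods: estimation trials use −Σₜ log p(x̂ₜ|xₜ) via any of
the three density routes (the numeric route includes the log-derivative term);
2AFC trials use the Bernoulli likelihood with probabilities clipped to
[10⁻⁹, 1−10⁻⁹]. Trials are grouped by condition (label → σ) so multi-reliability
designs fit one σ per condition.

Optimization is multi-start Nelder–Mead on unconstrained coordinates: softmax
weights with the first logit pinned at zero (removing the redundant degree of
freedom), log γ, log σ, raw ν. Default 10 seeded starts; the reported fit is
the best start, and the per-start NLLs are kept for diagnosing multimodality.
Constrained parameterizations reduce the search space:

* `zero_mean` — all νᵢ = 0 with a fixed SD ladder (default for heavy-tailed
  recovery: six SDs log2-spaced on [2⁻², 2³]); suits priors known to decay
  monotonically from zero.
* `tiled` — fixed, evenly spaced means and SDs, weights only (default for
  arbitrary shapes: nine components on [−4, 4] with SD equal to the spacing).
  Recovered shapes depend somewhat on the tiling, which is the price of the
  flexibility.

With 2AFC data from a single noise condition the prior scale and σ trade off
exactly; the fitter warns and the user should add a second reliability
condition. Even with two conditions the prior SD is only weakly identified
when the induced bias is close to 1: the 2AFC likelihood for a zero-mean
single-Gaussian observer depends on the data only through four probit
coefficients, and inverting them for γ divides by (α₁/α₂ − 1). Recovery
simulations should therefore expect γ estimates an order of magnitude less
precise than σ estimates at realistic trial counts; the noise SDs themselves
recover to a few percent from ~5000 trials.

## Synthetic data

`make_gridded_prior` tabulates reference priors that are *not* mixtures — a
standard Cauchy (truncated to ±25 and renormalized, raising the peak ~2.5%
above 1/π) and the normalized sum of two unit-SD Gaussians at ±2 — so that
fitting tests are genuine misspecification tests, not self-fits.
`simulate_point_estimates` draws stimuli from the gridded prior by inverse-CDF
sampling, adds Gaussian measurement noise, and reads the BLS estimate off a
1501-point table of gridded-posterior means, interpolating between tabulated
measurements. `simulate_2afc` pushes measurement pairs through the exact
posterior-comparison rule. Both are deterministic given a seed. The generating
noise level for the prior-recovery studies defaults to σ = 0.5 (half the Cauchy
scale; a regime where the prior visibly biases estimates without drowning the
stimulus). What these simulations do not emulate: lapses, motor noise,
sequential effects, learning, or heteroscedastic sensory noise — passing
recovery tests shows the inference machinery is correct, not that real
observers satisfy the model.

## Approximation benchmark

`sample_configs` draws stimulus/observer populations from two recipes. The
heavy-tailed recipe: stimulus anchors uniform on [−1, 1]; σ₁, σ₂ uniform on
[10⁻³, 1] (the lower edge avoids degenerate zero-noise draws); γ₁ pinned at
1.1·max(σ₁,σ₂); γ₂ uniform on [1.25, 3.25]·max(σ₁,σ₂); weights uniform and
normalized. The bimodal recipe instead draws component means from [−1, −0.5]
and [0.5, 1] with SDs in [1, 1.4]·max(σ₁,σ₂), guaranteeing two peaks. The
heavy-tailed recipe's bias ratio is analytically confined to
[1.21/2.21, 2.21/1.21] ≈ [0.548, 1.826]; 5000 draws reach ≈ [0.549, 1.825],
matching the range of biases reported for human speed and distance judgments.

For each configuration the benchmark sweeps the comparison stimulus over 15
points spanning the (approximate) PSE ± 3√(σ₁²+σ₂²) — covering the full rise
of the psychometric function — and evaluates the numeric reference, the
frozen-weight approximation, and the single Gaussian obtained by moment
matching the mixture prior (ν = Σwᵢνᵢ, γ² = Σwᵢ(γᵢ²+νᵢ²) − ν²). Errors are
pooled into 20 equal-width bins of the numeric probability; empty bins are
reported as missing, not zero. Configurations whose approximate psychometric
function never crosses ½ on the search interval are skipped and counted. The
default benchmark size is 500 configurations (the full study uses 5000, behind
a flag/CLI option); at either size the qualitative results are stable: the
frozen-weight approximation has several-fold lower RMS error than the
single-Gaussian replacement, is essentially exact near the PSE, and errs
toward steeper psychometric functions (positive signed error on the upper
flank, negative on the lower).

## Numerical choices and limitations

* Weight vectors must sum to 1 within 10⁻⁹ at construction (silently
  renormalized; larger deviations raise), and to 10⁻¹² after adjustment.
* All simulators and fits take explicit seeds; identical seeds give
  byte-identical outputs.
* The frozen-weight approximation degrades away from the PSE and is worst for
  bimodal priors; for final inference on bimodal data use the numeric routes.
* MAP-based 2AFC decision rules, asymmetric losses, lapse/guess parameters,
  m-AFC with m > 2, and hierarchical subject models are out of scope.
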