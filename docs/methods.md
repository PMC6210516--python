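# Methods

This note records the statistical models implemented in `leadgwqr`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot say about real surveillance data.

## 1. Quantile regression core

The τ-quantile of a sample minimises the total check loss
ρ_τ(r) = τ·r⁺ + (1−τ)·r⁻. `sample_quantile` returns the lower endpoint
when the minimising set is an interval (n·τ integral), matching the
left-continuous inverse CDF Q(τ) = inf{y : F(y) ≥ τ}.

`LinearQuantileRegressor` minimises Σ ρ_τ(yᵢ − xᵢ'β) exactly as a linear
program. The implementation solves the **dual**: maximise y'a subject to
X'a = 0, aᵢ ∈ [τ−1, τ]; the coefficient vector is the negated vector of
equality-constraint marginals. The dual has only p+1 equality rows, making
it several times faster than the split-residual primal for the
bootstrap-heavy workloads here; the primal is retained and the test suite
asserts both give the same optimum. With degenerate (flat) optima the
solver's vertex solution is returned. Weighted problems use the
homogeneity ρ_τ(c·r) = c·ρ_τ(r) (c > 0): rows of X and y are scaled by
their weights and solved unweighted.

Rates are modelled directly on [0, 1] with no link or transform. Fitted
upper-quantile planes can therefore leave [0, 1] at covariate extremes;
predictions are reported unclamped, as linear quantile models conventionally
are.

**Inference.** Paired (x, y) bootstrap, default B = 1000 (smaller in the
pipeline defaults, see §5): SE = replicate SD, 95% CI = percentile
interval, p-value = two-sided normal approximation on β̂/SE. The paired
bootstrap was chosen because it is assumption-free — consistent with the
reason one reaches for quantile regression in the first place (no
Gaussian-error assumption). Replicates whose resampled design is
degenerate are dropped; more than 20% dropped is an error. Rank-inversion
CIs and quantile-crossing constraints are out of scope.

**Standardized coefficients (STB)** are the slopes of a refit on
z-scored predictors and response; they rank predictors on a common scale.

## 2. GWQR

At each regression point the local coefficient vector minimises
Σ W₀ᵢ ρ_τ(yᵢ − xᵢ'β), W₀ᵢ = K(d₀ᵢ/h). Kernels: gaussian
exp(−½(d/h)²) (default) and bisquare (1−(d/h)²)² with compact support;
fixed-distance bandwidth by default, adaptive k-nearest-neighbour
optional. The gaussian default follows the common practice of the SAS
GWR/GWQR macro lineage. Observations with weight below 10⁻⁶ of the
maximum are dropped from a local fit for LP conditioning; a location with
fewer than p+2 usable observations is flagged non-converged (NaN
coefficients) without aborting the surface.

One bandwidth is used per (τ, fit); per-coefficient bandwidths are not
supported. Whether the bandwidth is shared across quantiles or reselected
per τ is a pipeline switch (`bandwidth_per_tau`, default off: one shared
bandwidth, selected at the middle quantile, mirroring the practice of
carrying a single bandwidth across the quantile set).

**Local inference** is a per-location weighted paired bootstrap
(default B = 199 at the API, 99 in the pipeline): rows inside the kernel
window are resampled with replacement keeping their kernel weights, the
local model is refitted, SE = replicate SD, t = β̂/SE, and |t| > 1.96
(strict) marks a location significant. The reference GWQR formulation
defers local standard errors to external derivations; the bootstrap is the
assumption-free stand-in and is seeded for exact reproducibility.

## 3. Bandwidth selection

**Quantile AIC grid search.**
AIC(h) = 2n·ln(σ̂_τ(h)) + 2·ENP(h), minimised over a candidate grid with
ties broken toward the smaller bandwidth. ENP(h) is the trace of the
weighted-least-squares pseudo-hat matrix built from the same kernel
weights — quantile regression has no exact hat matrix, and the WLS trace
preserves the bias–variance tradeoff (ENP → p+1 as h → ∞).

σ̂_τ(h) is the mean check loss of **leave-one-out local predictions**:
each location is scored by a local fit whose own kernel weight is zeroed.
This departs from the in-sample definition deliberately. Local quantile
fits interpolate p+1 points per window, so the in-sample check loss
collapses monotonically as h shrinks and an in-sample criterion always
selects the smallest candidate; the ENP penalty (any smooth-hat penalty)
is too weak to compensate. With the out-of-sample σ̂ the criterion behaves
as a bandwidth selector should: stationary fields push the choice to the
top of the grid, genuinely varying coefficient surfaces pull it down.

**Variogram route.** The empirical semivariogram
γ(d) = Σ_{N(d)}(zᵢ−zⱼ)²/(2|N(d)|) is computed on 15 equal-width bins up to
half the maximum pairwise distance; gaussian, spherical and exponential
models (nugget, partial sill, range) are fitted by least squares weighted
by pair counts and compared by AIC = n_bins·ln(RSS/n_bins) + 2·3. The
practical range of the winning model (gaussian a√3, exponential 3a,
spherical a) is the suggested bandwidth. Candidate value vectors are the
observed rate or residuals from global fits. A near-pure-nugget fit
(partial sill < 5% of the sill, or a range beyond 1.5× the largest lag) is
flagged `range_reliable=False`. On the default generator this route
produces bandwidths of roughly 2–3 km, the scale of the smooth fields the
generator plants.

## 4. Spatial diagnostics

**Nonstationarity.** Per coefficient and quantile: mean, median, min, max
and IQR of the local estimates are compared against the global bootstrap
SE; IQR **strictly greater** than 2·SE ⇒ "Nonstationary" (boundary ties
are "Stationary", reading "twice as large" strictly). The rule is exactly
recomputable from the summary columns.

**Moran's I** with E[I] = −1/(n−1) and the closed-form
normality-assumption variance (z-scores of the magnitude reported for
areal surveillance data imply the analytical, not permutation, variance);
a randomization variance is not implemented. Weights default to
row-standardized k-NN (k = 8) on block centroids — the areal units are
represented as points, so contiguity is not defined; a symmetric
distance-band scheme is the alternative. Exact distance ties in k-NN break
toward the smaller index (stable sort), making weight matrices fully
deterministic.

## 5. Synthetic generator

The generator emulates what the analysis assumes about block-level
lead-screening data:

- **Coordinates**: jittered lattice over an 8 × 8 km extent (planar
  meters, Euclidean distances, no CRS); at n = 1393 the median
  nearest-neighbour spacing is ~200 m, compatible with kernel bandwidths
  of 2–3 km.
- **Covariates**: a Gaussian copula with smooth spatial structure. Three
  latent fields (weight `spatial_smoothness` = 0.5 on random-phase cosine
  superpositions with 1.5–6 km wavelengths, the rest white noise) are
  empirically orthonormalised and given a Cholesky-imposed latent
  correlation, then pushed through the marginals: building year normal
  (1923, 17.6) truncated to [1860, 1978]; taxable value and soil lead
  lognormal matching mean/SD (58.445, 23.815) K$ and (185.8, 112.5) ppm.
  The latent correlations are analytically pre-compensated for the
  lognormal transforms so the observed-scale correlations land on
  (−0.54, +0.40, −0.38); orthonormalisation makes the realised latent
  sample correlation exact, leaving only the (small) transform-induced
  sampling noise.
- **Response**: latent risk = linear predictor (stationary defaults:
  intercept 4.462, year −0.002, log-tax −0.15, soil +4·10⁻⁴ — the signs
  of the substantive findings) plus heteroskedastic Gaussian noise with
  SD = noise_scale·(0.098 + 2.55·max(η−η̄, 0)). The lowest
  `zero_inflation` = 45% of latent risk is set to exactly 0 — zeros
  cluster in low-risk areas rather than being sprinkled independently —
  and the rest is clamped to [0, 1]. Screening counts are uniform on
  [5, 40] per block (unreported in the motivating data; only rates are
  modelled) and the rate is re-expressed as n_elevated/n_tested, so the
  count identity holds exactly. The intercept and the two noise constants
  were calibrated once, by least squares over 12 seeds, against the
  marginal targets mean 0.1375 and quantiles (0.05, 0.18, 0.40) at
  τ = (0.5, 0.75, 0.9); the published median is printed as 0.04 in prose
  and 0.05 in the distribution table — the generator targets the tabled
  0.05. The risk-proportional noise both right-skews the rate and makes
  fitted slopes steepen in |τ|, reproducing the qualitative
  quantile-profile of the published coefficients.
- **Varying mode** replaces any coefficient by a smooth surface β_k(u, v)
  (defaults: ±60% sinusoidal modulation; `step_surface` builds
  west/east steps for recovery tests).

**What passing tests do not show.** The generator draws covariates from a
smooth copula and a linear latent risk; real surveillance data have
irregular census-block geometry, non-residential gaps (edge effects are
explicitly not corrected), measurement error in soil sampling, and
count-driven heteroskedasticity (binomial denominators of 1–100+, not
uniform 5–40). Calibration tests show the machinery recovers what it
assumes; they do not validate the linear-quantile model itself against
real lead-poisoning data, and published coefficient tables from
confidential data are not reproducible here.

**Recovery-study conditions.** Zero inflation plus the [0, 1] clamp censor
nearly half the sample, which attenuates median-regression slopes — a real
feature of zero-inflated rates, not an artifact. Parameter-recovery and
nonstationarity-power studies therefore run the generator uncensored
(zero_inflation = 0, intercept +0.40, noise_scale 0.3), planting a
soil-lead step of 1.2·10⁻³ at the extent midline; with n = 400 and a
3.2 km gaussian bandwidth the IQR-vs-2SE rule flags the planted
coefficient and clears the constant nuisance ≥ 80% of the time. Problem
sizes across the suite (n = 100–400 for surface fits, 1393 for
calibration, B = 50–150 for bootstrap checks) were chosen as the smallest
that leave clear Monte-Carlo margins.

## 6. Numerical conventions

- All randomness flows from explicit seeds; the pipeline splits one master
  seed per stage and quantile (SHA-256 of "seed:stage:tau", 31 bits), so
  reruns are byte-identical.
- LP tolerance: vertex solutions from HiGHS; oracle tests compare
  objectives at 10⁻⁸, coefficient reductions at 10⁻⁶.
- Pipeline defaults trade bootstrap depth for wall time (B = 200 global,
  99 local); raise them for publication-grade intervals.
- Degenerate inputs: empty samples, τ ∉ (0,1), non-positive-definite
  correlation targets, rank-deficient designs (the offending column is
  named), constant Moran inputs and degenerate extents are all rejected
  with explicit messages; near-constant residual vectors in the Moran
  report become NA rows rather than errors.
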