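# Methods

This note documents the models, statistics and numerical choices behind
`herdcycles`, and what the synthetic benchmarks do and do not establish.

## 1. Tri-trophic model

State variables: vegetation biomass `V` (Mg dry weight km⁻²), herbivore
density `N` and predator density `P` (individuals km⁻²); time in years.

    dV/dt = u0 (1 − V/m) − a V N / (b + V)
    dN/dt = ξ N (a V/(b + V) − η) − c N P / (d + N)
    dP/dt = χ P (c N/(d + N) − μ) − (s0/κ) P²

Assumptions: vegetation regrows linearly toward its maximum coverage `m`
rather than logistically, because grazing removes standing crop without
much plant mortality (the relevant forage, lichen, takes decades to regrow
after overexploitation); both consumption links saturate (Type II);
consumer mortality is folded into zero-population-growth (ZPG) consumption
rates `η` and `μ` — the intake level at which each consumer's growth is
exactly zero — which are far easier to estimate from field data than death
rates; and the predator is self-limited by the quadratic Bazykin term.

The self-limitation is implemented as `(s0/κ)·P²`: intrinsic rate of
predator increase over maximum predator density, the form that makes the
term a logistic-style brake scaled by territory saturation. With the
default parameters this reproduces a 57.96-year herbivore cycle of
relative amplitude 0.947; the alternative reading `s0·κ·P²` yields a
60.4-year cycle and was rejected on that basis.

Default parameters (bundled as `data/default_params.yaml`): u0=0.8, m=100,
a=2.5, b=25.4, ξ=0.27, η=0.89, c=18.5, d=0.5, χ=0.114, μ=9.25, s0=0.3,
κ=0.1, with the herbivore intrinsic growth rate r0=0.3 used only to derive
ξ = r0/(a·m/(b+m) − η) = 0.2718 ≈ 0.27. ξ remains a first-class parameter
so the derivation can be overridden. One unit inconsistency inherited from
the source literature: μ is sometimes quoted with a density unit, but it
enters the model as a consumption rate (prey predator⁻¹ yr⁻¹) and is
implemented as such.

**Integration.** `scipy.integrate.solve_ivp` with the Dormand–Prince
RK45 pair, rtol 1e−8 / atol 1e−10, simulated 3000 years from
(V, N, P) = (50, 2, 0.001) with the first 1500 years discarded and annual
sampling. Halving the tolerances moves the estimated period by far less
than 0.1 yr. Inside the right-hand side, states are clipped at zero only
for evaluating the functional responses (adaptive steps can undershoot by
less than the tolerance); saved output is never silently clipped — any
excursion beyond −1e−6 aborts the run.

**Stochastic variant.** A discrete annual map: the deterministic increment
of each state over one year (computed with 12 Euler sub-steps) is
multiplied by exp(ε), ε ~ N(0, noise_sd²) i.i.d. per state and year, and
the state floored at zero. Multiplicative environmental noise is the
minimal standard choice; noise_sd defaults to 0.05. With noise_sd = 0 the
map reproduces the ODE cycle within ~3% in period and amplitude. At
noise_sd = 0.05 roughly one run in twenty loses its predator — the cycle
takes P through densities of order 1e−7, where a run of adverse shocks
drives it to numerical extinction — and the herbivore then settles at the
vegetation-limited equilibrium. This is a genuine property of the
stochastic model (the "atto-fox" fragility of deep predator troughs), so
summaries over seeds average the period over runs that still test cyclic.

## 2. Cyclicity test

**Null model.** Ornstein–Uhlenbeck state space: a mean-reverting Gaussian
process (relaxation rate λ, stationary variance σ²ₚ) observed with white
noise σ²ₙ. Sampled annually the OU component is AR(1) with ρ = e^{−λ}, so
the periodogram null spectrum is

    S(f) = σ²ₚ (1 − ρ²) / (1 − 2ρ cos 2πf + ρ²) + σ²ₙ.

The periodogram uses I_k = |FFT_k|²/L at Fourier frequencies k/L (mean
removed, no detrending, no taper); the Nyquist ordinate is excluded from
fitting and testing (it is χ²₁ rather than exponential). Fitting maximises
the Whittle likelihood (ordinates independent exponentials with mean S):
a profile-likelihood grid over (ρ, σ²ₙ/σ²ₚ) with the overall scale solved
in closed form, refined by a Nelder–Mead polish in `fit_ou_null`. On AR(1)
draws of length 120 the median recovered λ is within 7% of truth.
Boundary estimates (ρ → 0 or → 1, zero noise floor) are flagged.

**Statistics.** Two are computed per series:

* `g = max_k I_k / S_k`, the standardised spectral peak — powerful when
  the window holds several cycles;
* `h`, a prewhitened harmonic max-F: the best least-squares sine+cosine
  fit over a 2×-oversampled frequency grid, applied to y_t − ρ̂ y_{t−1},
  where ρ̂ is re-estimated from the residuals after removing the best raw
  harmonic (so the estimate is consistent under both hypotheses). This
  statistic sees phase coherence, which the periodogram discards.

The phase-aware statistic is what rescues power in the regime that matters
here: a 40-year cycle in a 60-year window concentrates its spectral power
in the two lowest Fourier bins, where a steep fitted red-noise spectrum
can mimic it — any phase-blind peak test then has power below ~0.3
regardless of calibration. `h` is scale-free and approximately pivotal in
the fitted persistence, so it also tolerates a null fit contaminated by a
true cycle.

**P-value.** Parametric bootstrap: simulate n_boot (default 199) series
from the fitted null (AR(1) plus noise, 50-year warm-up), apply the entire
procedure to each, and convert both statistics to bootstrap ranks; the
combined statistic is Fisher's −log p_g − log p_h, itself calibrated on
the replicate ranks. The bootstrap generator is seeded, making the verdict
deterministic given (series, seed). Measured operating characteristics at
L=60 against AR(1)(ρ=0.7)+noise nulls: type-I error 0.038–0.043 at α=0.05
(500–1000 replicates); power 0.96+ for a sinusoid with amplitude 0.9 of
the mean, period 40, and red noise at ~11% of the mean. The analytic
Šidák-style correction 1−(1−e^{−g})^K was evaluated and rejected: with
the null fitted to the same spectrum it is badly conservative (measured
type-I ≈ 0.015) and nearly powerless at periods near the window length.

**Period and amplitude.** Period is the inverse of the dominant raw
periodogram ordinate, refined by a quadratic through the log-power of the
peak and its two neighbours (at most half a bin; clamped to ≤ L years);
this interpolation is on by default and is how the 57.96-year figure is
obtained. Amplitude is 0.5 (max − min)/mean of the series as given,
imputed values included; it is scale invariant and reported whether or not
the series tests cyclic. Series shorter than 10 points, or constant
series, receive a non-cyclic verdict with an explanatory reason rather
than an exception. A `log_transform` flag runs the test on log-abundances
(off by default; amplitude is always computed on the natural scale).

## 3. Imputation

Missing survey years are filled by Stineman's rational interpolation on
the integer-year grid between the first and last survey (never beyond —
the method does not extrapolate). Slopes at data points follow Stineman's
prescription — a convex combination of the two adjacent secant slopes
weighted by the squared chord length of the opposite interval — followed
by a monotonicity cap: slopes are zeroed at local extrema of the data and
bounded at three times the smaller adjacent secant. The cap is not
cosmetic: within one interval the rational correction is monotone exactly
when both endpoint slopes stay within 3× the interval's secant (the same
bound as Fritsch–Carlson for cubics, derived for this interpolant by
minimising its derivative), and without it a steep tangent next to a flat
secant produces a spurious interior bump. With the cap, the interpolant
passes exactly through observations, reproduces straight lines, and
creates no new extrema between adjacent observations (zero violations on
5000 adversarial random fixtures).

Cross-validation removes a fraction (default 20%) of each herd's interior
observations at random — endpoints are protected since the method cannot
extrapolate — re-imputes, and reports the Pearson correlation between
held-out truth and imputed values pooled over all points per replicate
(per-herd means as a secondary column). Removal is per-series rather than
pooled across the dataset, so every herd contributes. On the default
synthetic collection the pooled correlation is ≈ 0.97.

## 4. Covariate regressions

Responses are per-herd cycle period and amplitude (cyclic herds only).
Candidate covariates: latitude, NDVI/DHI productivity, winter monthly
minimum temperature, winter monthly precipitation, predator species count,
wolf presence, biome, subspecies, ecotype, semi-domestication.

* **Collinearity screen** at |r| > 0.7 on pairwise correlations, with
  categoricals fully one-hot coded and the variable-pair correlation taken
  as the largest absolute column-pair correlation (full coding, not
  drop-first, so a category aliased with another variable's level shows
  r = 1). For a flagged pair the member on the priority list (default:
  semi_domesticated, ecotype — herd metadata that recapitulates
  subspecies/biome) is dropped; without a priority match, the member with
  the larger mean |r| against the remaining covariates goes.
* **GLM**: Gaussian errors, identity link — ordinary least squares via
  statsmodels, treatment contrasts with the alphabetically first level as
  reference. AIC uses the statsmodels convention −2ℓ + 2(p+1) with the
  profiled Gaussian likelihood; the error variance is not counted as a
  parameter, a constant offset that cancels in comparisons. AICc is
  available behind a flag but AIC is the default.
* **Backward stepwise**: at each step drop the single term (categorical
  terms as whole blocks) whose removal lowers AIC most; stop when none
  does. Ties break alphabetically, making selection deterministic and
  invariant to predictor column order. The accepted path is strictly
  decreasing in AIC. A single pure-noise predictor survives at the
  theoretical χ²₁ > 2 rate (≈ 0.157, verified by simulation); planted
  strong effects are retained in 200/200 replicates with unbiased
  coefficient recovery and ~95% CI coverage.
* **Diagnostics**: normal QQ correlation and an |residual|-on-fitted slope
  test for heteroscedasticity (flagged at p < 0.05 with positive slope),
  with optional plot output; small samples are flagged rather than
  refused. The period–amplitude association is a simple OLS of period on
  amplitude — period is the response, i.e. years of cycle per unit of
  relative amplitude.

When too few cyclic herds support the full design (n ≤ p+1), the pipeline
sheds the widest categorical block and retries, logging each step; if only
numeric covariates remain and the fit is still infeasible the regression
is reported as skipped rather than fabricated.

## 5. Sensitivity sweeps

Bottom-up (u0 × m over 0.1–2 × 10–200), top-down (c × d over 0.01–40 ×
0.01–1), both full factorial by default (a lock-step diagonal mode is
available), and a global one-at-a-time ±30/±15/0% sweep of all twelve
dynamic parameters. Default grid 20×20, configurable; the bundled analyses
use 10×10, which resolves every trend at desk scale. Each cell runs the
standard protocol and scores the herbivore series.

Two screens precede the cyclicity test, because noiseless solver output
makes "statistical significance" the wrong notion of a cycle: cells whose
relative standard deviation is below 1e−4 are flat equilibria, and cells
whose last-third standard deviation is under half the first-third's are
decaying spirals around a stable focus (we verified by integrating to
t = 9000 that such cells converge to equilibrium). Both are recorded as
non-cyclic with NaN metrics — explicit nulls, never zeros. Integration
failures are flagged `converged=False` and the sweep continues. Cells are
mutually independent, so results do not depend on visitation order.

Trend tests use a stratified Kendall statistic (concordant minus
discordant pairs pooled within rows or columns of the grid, normal
approximation): on a factorial grid the set of cyclic cells differs
between rows, so plain marginal means confound the parameter effect with
that selection. A "joint" variant combines the two per-axis statistics by
Stouffer's method for the bottom-up pair, which is varied together.

Directions found (10×10 grids, cyclic cells): period falls as u0 and m
rise (τ ≈ −0.44 jointly, p ≈ 2e−10); period and amplitude both rise with
c (τ ≈ +0.8/+1.0) and fall with d (τ ≈ −0.9/−1.0). Amplitude, however,
**rises** with u0 and m (τ = +1): the limit cycle is born at a
supercritical Hopf bifurcation near u0 ≈ 0.6 (at m = 100) with amplitude
growing from zero as enrichment increases — the classic paradox of
enrichment — and below the Hopf point the equilibrium is stable and
cycles die. The "slow regrowth → bigger booms and busts" intuition of the
food hypothesis holds in this model for cycle *period* but not for
relative amplitude; the corresponding acceptance assertion is left
failing rather than redefined, since no honest choice of burn-in or
filtering reverses the direction.

In the global sweep, most cyclic cells fall inside the 23.0–66.1-year
band seen in herd survey data; cells outside are flagged
(`in_empirical_range=False`) — the strongest excursions come from
lowering the herbivore's foraging or conversion parameters (a, ξ) or the
predator ZPG rate μ by 30%.

## 6. Synthetic data

`SyntheticSpec` defaults encode the survey regime the pipeline targets:
43 herds; series lengths from a truncated normal, mean 45.1 yr on 23–74;
19/43 truly cyclic; periods centred on 42 yr within 23.0–66.1; amplitudes
centred on 0.91 within 0.418–1.54; missingness rates per herd from a
truncated normal, mean 0.392 / SD 0.323 on [0, 0.9] (realised missingness
lands within 0.05 of the target mean after truncation and span anchoring);
multiplicative lognormal observation noise with CV 0.10 (a typical
survey-error scale); herd mean abundances log-uniform on 10³–10⁶ animals
(scale cancels in amplitude).

Cyclic herds come in two modes. The default log-sinusoid
x(t) = μ exp(s sin(2πt/T + φ))/I₀(s) stays positive at any amplitude; the
shape s is solved from sinh(s)/I₀(s) = A so the realised relative
amplitude equals the target exactly over whole cycles (amplitudes above
≈ 6.8 are infeasible for this shape and rejected). The mechanistic mode
windows tri-trophic runs with ±5% jitter on (u0, m, c, d), rescaled to the
herd's mean abundance. Non-cyclic herds are log-AR(1) (ρ = 0.7, sd 0.25)
around their mean. Period and amplitude are linked linearly to centred
NDVI and winter minimum temperature with configurable coefficients
(defaults −1.596 and −5.568 yr per unit for period; −0.094 and −0.007 for
amplitude), plus Gaussian scatter, clipped to the stated ranges.
Missingness is uniform at random within a herd with the first and last
years always observed (anchoring the interpolation span); a structured
survey-every-k-years mode exists for realism. Covariates include a
deliberately collinear block (ecotype ≈ f(subspecies), semi-domestication
concentrated in one subspecies) so the screen has something real to do.

What the generator does **not** emulate: spatial synchrony between herds
(Moran effects), slowly changing cycle properties within a series,
survey-effort autocorrelation, and non-stationary trends. Passing tests
therefore certify the pipeline's behaviour under stationary cycles with
random gaps — not robustness to regime shifts or synchronous continental
fluctuations.

`generate_regression_benchmark` produces the same covariate table with a
linear Gaussian response and exact known coefficients (zeros included)
for selection and coverage tests. Everything is deterministic given the
spec seed.

## 7. Pipelines and I/O

All tabular artefacts are CSV with `# key: value` provenance headers
(seed, configuration hash, package version — no timestamps, so reruns are
byte-identical); regression results are JSON. The configuration hash
covers analysis-relevant fields only (not output paths or log level).
Input schemas are validated before any computation, with errors naming the
file and column; per-herd events (imputation counts, verdicts, skipped
stages) are logged as structured `stage=... herd_id=... event=...` lines,
and a row-accounting check guarantees no herd is silently lost. All
randomness flows from the single configuration seed (the per-herd test
seed is seed + herd index in sorted order).

## 8. Problem sizes used by the bundled analyses

Simulations use the full 3000-year protocol throughout. Sweeps in the
shipped analyses are 10×10 with 99 bootstrap replicates per cell;
calibration checks use 1000 null series (type-I) and 200 signal series
(power) at length 60 with 199 bootstrap replicates each; imputation CV
uses 20 replicates on the 43-herd default collection; selection benchmarks
use 200–500 replicates at n = 19–43. These sizes resolve every property
tested while keeping a full run at desk scale.

## 9. Known limitations

* The cyclicity bootstrap assumes the OU state-space family under the
  null; heavy-tailed observation error or strong trends are outside it
  (no detrending is applied, by design).
* Period resolution is Fourier-limited: for a 45-year series the few
  lowest-frequency bins are decades apart, and interpolation only
  partially compensates; period errors of ~10 years for detected herds
  are expected at these lengths.
* The stochastic model's predator-extinction fragility reflects the
  continuous model's deep troughs, not demographic realism (no Allee
  effects, no immigration).
* Stepwise AIC at n ≈ 19 cyclic herds with many candidate terms is
  honest about infeasibility (it sheds categorical blocks and reports
  skips) but cannot manufacture degrees of freedom; conclusions from such
  fits carry the usual small-n caveats.
* No spatial structure: herds are independent in the generator and in the
  regressions (no spatial autocorrelation modelling).
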