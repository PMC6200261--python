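# Methods

## The prediction model

All forecasts come from lag-`l` multiple linear regressions
`y_i = α₀ + Σₙ αₙ x_{i−l,n} + ε_i`, where the predictand `y` is an annual
anomaly series (stock biomass or recruitment) and each predictor `x_n`
leads it by `l` years. The lead is what creates the forecast horizon: a
predictor observed through year `T` supplies regressor values for target
years up to `T + l`, so the model genuinely predicts `l` years beyond the
data. By default every predictor in one model shares the same lead (7 years
for the stock, 5 for recruitment, matching where the lagged correlations
peak); per-predictor leads are supported for structural models such as the
generating design of the synthetic scenario.

Anomalies are departures from the mean over a fixed baseline window
(configurable; the full predictand span by default). Detrending is applied
during correlation screening but *not* to series entering prediction
models — the low-frequency variations are a large part of what the models
should predict — and both choices are configuration switches
(`detrend_screening`, `detrend_prediction`).

Fitting is ordinary least squares (`numpy.linalg.lstsq`; residual SD with
the `n − p − 1` denominator). Rank-deficient designs are an error that
points the caller to `orthogonalize_predictors`, which successively
residualizes each predictor on its predecessors (order-dependent, so the
listed order is authoritative); orthogonalization changes coefficients but
not fitted values, and the stored affine transform lets an orthogonalized
model predict from raw predictor values.

### Prediction intervals

The 95% interval uses the standard OLS predictive variance
`s²(1 + x₀ᵀ(XᵀX)⁻¹x₀)` with a two-sided t quantile — residual variance plus
parameter uncertainty. Whether the parameter term belongs in the interval
is a genuine design choice; both half-widths are computed (`pi_half`,
`ci_half`) and the full predictive variance is the default, verified
against a parametric-bootstrap oracle in the tests (agreement within 10% at
n = 60). The ensemble spread shown alongside is the per-year min–max of
predictions from the cross-validation ensemble — a robustness envelope, not
a probability interval.

## Skill evaluation

Two metrics: the anomaly correlation `r` and the variance-ratio Brier score
`β = 1 − var(y − ŷ)/var(y)` (both variances with `ddof=1`; β ≤ 1,
unbounded below; this is a deterministic skill score, not the probabilistic
Brier score that shares the name).

Cross-validation draws a uniform random 80% of design rows (without
replacement, non-contiguous years allowed) to fit, scores fit and held-out
rows, and repeats 1000 times (configurable); medians and inter-quartile
ranges are reported per period. Iterations whose held-out set has fewer
than 3 rows or whose fit subset is rank-deficient are redrawn, counted, and
capped at 10× the iteration budget. Benchmarks run inside the same
protocol: the random-chance (RC) model re-shuffles every predictor column
independently each iteration before fitting, and lag-`l` persistence skill
is the correlation of the observed series with itself shifted `l` years
over the design span. The RC prediction-period correlation is centered on
zero by construction; note that with ~10-row held-out sets the *absolute*
null correlation is typically ≈ 0.2 (≈ 0.674/√(n−1)) — the meaningful null
statements are the near-zero median and an IQR bracketing zero.

Residual diagnostics follow standard practice: Durbin–Watson
(≈ 2(1 − ρ₁); computed over consecutive-year runs when training years have
gaps), Shapiro–Wilk normality, and the correlation of |residual| with
fitted values for homoscedasticity. Diagnostic failures warn rather than
abort — serial correlation inflates nominal significance but does not bias
the coefficients, and the cross-validation's random subsetting breaks most
of the residual autocorrelation; the robustness check of fitting on every
second data point is exercised in the tests.

## Significance testing

Correlation significance uses random-phase (Fourier) surrogates of the
predictor: the amplitude spectrum is kept, phases are drawn uniformly
(conjugate-symmetric; mean and Nyquist components preserved), and the
observed `r` is compared with the surrogate null, two-sided, with the
`(1 + k)/(1 + N)` continuity correction. This preserves the predictor's
autocorrelation, where a naive t-test badly over-rejects for red series
(type-I error > 0.2 at AR(1) ρ = 0.9 vs ≈ 0.05 for the surrogate test).
Defaults: 1000 surrogates, α = 0.05 two-sided — the surrogate count and
sidedness are this package's documented choices.

Two multiplicity modes exist for profile-level flags. Per-lag testing
matches the convention of significance stars in a lag table. The
error-attribution step instead scans a lag window for a peak, so its flags
use the max-|r| surrogate null over the window (maxT), controlling the
family-wise error — with six per-lag tests at α = 0.05 the chance of a
spurious flag somewhere would be ≈ 0.2 even for unrelated series.

## The synthetic scenario

The generator plants exactly the structure the regression framework
assumes, with closed-form ground truth:

* upstream index: AR(1), lag-1 coefficient 0.7, unit marginal SD
  (innovations scaled by √(1−a²), 100-step burn-in) — the red, slowly
  varying basin-scale SST index;
* advective links: `target_t = gain·source_{t−lag} + noise`, lags 3 years
  (upstream → inflow, gain 0.9, noise SD 0.7) and 1 further year
  (inflow → Barents opening, gain 0.9, noise SD 0.5), so the opening lags
  the upstream index by 4 years; the first `lag` target years are missing,
  never wrapped;
* stock: `0.6·FSC_{t−4} + 0.5·BSO_{t−3} − 0.6·HR_{t−2} + N(0, 0.8)`, i.e.
  a 7-year total lag to the upstream index, plus an independent AR(1)
  harvest-rate anomaly (coefficient 0.4, unit SD) whose negative effect
  leads by 2 years;
* recruitment: the stock's driver signal 2 years earlier plus heavier
  independent noise (SD 2.1), giving the weaker predictability real
  recruitment shows.

Gains and noise SDs are fixed defaults chosen so the implied link
correlations sit in the 0.5–0.8 range typical of observed hydrographic lag
tables, the stock equation explains >60% of variance (multiple correlation
ρ = 0.86 with the harvest term, 0.77 hydrography-only), recruitment
predictability is ≈ 0.5, and the harvest/error correlation is ≈ −0.6 — the
qualitative magnitudes of the real Barents system. Default record length is
60 years (labelled 1950–2009).

Because every series is a finite linear combination of lagged primitive
sources (upstream innovations, harvest innovations, link noises), any
cross-covariance is a double sum over source autocovariances (AR(1):
`σ²a^|k|`; white: `σ²δ_k`). `ScenarioTruth` carries the resulting
theoretical peak lags/correlations per link, the stock equation's multiple
correlation (with and without the harvest term), and the implied
harvest–error correlation; the tests verify these against brute-force
estimates on 5000-year realizations (±0.05).

What the generator does *not* emulate: seasonal structure, nonlinear or
density-dependent stock dynamics, time-varying gains or observation error
in the assessment series. Passing tests therefore demonstrate that the
machinery recovers what it assumes — linear, stationary, additively noisy
lag structure — not that the real stock obeys that structure.

## Numerical and interface choices

* Calendar years are first-class: series are stored on consecutive year
  labels with explicit NaN for missing years, and every lag is bookkeeping
  on labels, never index arithmetic on compacted arrays. Alignment is
  complete-case (listwise deletion); no imputation.
* The high-pass filter is the complement of a centered 5-year running mean
  (edges use the available window), chosen for transparency and exact
  `highpass + lowpass = original` complementarity; its Nyquist attenuation
  is only 1/5, so a period-2 oscillation retains 64% of its variance — a
  sharper (e.g. Butterworth) filter is a possible alternative but not the
  default.
* Peak-lag ties break toward the smallest lag (the most parsimonious
  lead). Unavailable lags (overlap < 10 years) stay in the profile as
  missing rather than being dropped.
* Surrogates are built on the predictor only (standard usage for this
  test); building on both sides would be a straightforward extension.
* All randomness flows from one root seed through
  `numpy.random.SeedSequence` spawning (stage-level streams for data,
  screening, prediction, attribution), making full pipeline outputs
  byte-identical across reruns; report files contain no timestamps.
* Problem sizes in the shipped analysis and acceptance script — 60-year
  records, 100 scenario replicates, 300–1000 cross-validation resamples,
  200–500 surrogates — keep every stage to seconds while holding
  Monte-Carlo error on reported aggregates near the second decimal.

## Known limitations

* The regression is purely statistical; it cannot distinguish advection
  from any other mechanism producing the same lag structure.
* Prediction intervals assume Gaussian, homoscedastic, serially
  independent errors; the diagnostics report when those assumptions are
  dubious, but the intervals are not corrected for serial correlation.
* Skill estimates on ~50-row designs carry substantial sampling spread
  (visible in the cross-validation IQRs); single-realization skill can sit
  well away from the population value.
* The operational-forecast comparison utility (`subsample_skill`) evaluates
  externally supplied forecast series; constructing such series from
  assessment reports is manual and outside the package.
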