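# Methods

This note documents the models implemented in `fragno2`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Problem and pipeline

The package quantifies how the fragmentation of urban functional land use
around air-quality monitoring stations is associated with the deviation of
observed NO₂ from its business-as-usual trajectory, and how an
anthropogenic-emission restriction (a COVID-19-style lockdown) mediates that
association. Five stages run per station:

1. **Counterfactual forecast.** A seasonal ARIMA model with exogenous
   regressors, SARIMAX(p,d,q)(P,D,Q)_s, is fitted to the pre-intervention
   NO₂ history with air temperature, relative humidity and wind speed as
   exogenous variables, and forecasts the evaluation window as if no
   intervention had occurred. Observed meteorology drives the forecast —
   exogenous variables are never themselves forecast.
2. **Training cutoff by MOPE.** The training/evaluation split is chosen among
   candidate cutoffs by the mean observed-predicted error,
   MOPE = (Σₖ |obsₖ − predₖ|/obsₖ)/n · 100, averaged over stations; the
   lowest mean wins and ties go to the latest cutoff (most training data).
3. **DTW variation score.** The divergence between observed and counterfactual
   NO₂ is the dynamic-time-warping cost
   min over warping paths of sqrt(Σ_k (t_act,i − t_con,j)²),
   with step set {(1,0),(0,1),(1,1)}, no window constraint and no path-length
   normalisation, computed separately before and during the lockdown
   (split at the lockdown date; the before window starts at the forecast
   start). Warping tolerates small timing lags that would inflate a
   day-to-day differential.
4. **Fragmentation metrics.** From the land-use raster inside a circular
   3 km buffer: edge density ED = Σe/A (m per ha of class area) and landscape
   shape index LSI = 0.25·Σe/√A (A in m², so a solid square scores 1) for the
   industrial and public classes; landscape-level aggregation index
   AI = 100·Σᵢ(gᵢᵢ/max gᵢᵢ)Pᵢ over developed classes and number of patches
   NP (8-connected components per class, summed).
5. **Association models.** Four Gaussian-family, log-link additive models of
   the variation score Y: UFB/UFD use the six fragmentation covariates
   linearly (before/during lockdown response); UFCB/UFCD add penalized
   B-spline smooths of ten controlling variables (population, AQI, PM₂.₅,
   PM₁₀, O₃, CO, SO₂, temperature, humidity, wind speed). A VIF screen
   (threshold 10) precedes fitting. The mediated impact of the emission
   restriction is read from the before-vs-during change in coefficient
   magnitude, Δ|β| = |β_during| − |β_before|, with a sign-agreement flag and a
   |Δβ| < 0.1 "limited impact" band.

## Modelling choices where the design was open

* **Seasonal period.** Daily series with both weekly and annual cycles:
  seasonal differencing/AR at lag 365 is numerically impractical, so the
  SARIMA kernel uses s = 7 and the annual cycle enters as one sin/cos
  Fourier pair of period 365.25 d appended to the exogenous set. Both are
  configurable (`seasonal_period`, `fourier_annual`).
* **Order selection.** A grid of 24 orders (six nonseasonal × four seasonal
  shapes) searched by AIC; stationarity/seasonality tests (ADF, Ljung–Box,
  Jarque–Bera) are exposed as diagnostics but do not gate the grid — AIC
  decides. Non-convergent orders are skipped with a warning; a station where
  every order fails is excluded from the association fits and listed in the
  run manifest.
* **Missing observations.** Gaps up to 3 days are linearly interpolated;
  longer gaps stay missing (the state-space fit handles missing values; MOPE
  excludes incomplete pairs). A zero observed value makes the relative error
  undefined and raises rather than being silently skipped.
* **"log E(Y)" with Gaussian errors** is implemented literally as a log-link
  Gaussian model (not an identity-link fit to log Y); the log-transform
  alternative is available as `log_transform_response` for sensitivity.
* **Smoothing level.** Each control smooth uses a B-spline basis
  (10 df, cubic by default); one shared smoothing parameter is scanned over a
  log-spaced grid and the AIC-minimising value kept. When the station count
  cannot support the spline bases (fewer than ~4 df per smooth after the
  linear terms), the controls enter linearly instead — the infinite-penalty
  limit — and this is logged. Basis dimension also shrinks with n so the
  penalized fit always has residual degrees of freedom.
* **Uncertainty and fit quality.** 95% CIs are Wald (±1.96·SE). R² is the
  squared Pearson correlation between fitted and observed response on the
  response scale; deviance explained is 1 − residual/null deviance. These are
  reported side by side because neither is canonical for penalized log-link
  models.
* **Metric conventions.** Rook adjacency for edges and like-adjacencies,
  8-connectivity for patches (the common raster-metric defaults). The ED/LSI
  denominator is the class area (per the metric definitions used here; a
  `landscape` denominator switch exists). Cell sides on the buffer boundary
  count as edge by default — clipping would otherwise deflate edge totals
  asymmetrically across stations. Background is excluded from AI and NP.
  A class whose maximal like-adjacency count is 0 (isolated single cells)
  contributes a fully-aggregated ratio of 1 to AI by convention.
* **Maximal like adjacencies.** For class area A (cells), with n = ⌊√A⌋ and
  m = A − n²: 2n(n−1) if m = 0; +2m−1 if 0 < m ≤ n; +2m−2 if m > n — the
  most compact arrangement (square plus partial row), each adjacent pair
  counted once. Verified against exhaustive polyomino enumeration for A ≤ 9.

## The synthetic-data generator

The generator emulates a national monitoring panel: by default 145 stations
with daily NO₂ from 2015-01-01 to 2020-05-01, a forecast window starting
2020-01-01 and a lockdown on 2020-01-24.

* **NO₂ law.** baseline (35 µg/m³) + annual cosine (amplitude 12 µg/m³,
  period 365.25 d, winter peak) + weekly sine (3 µg/m³) + linear meteorology
  effects centred on reference means + AR(1) noise (innovation SD 4 µg/m³,
  AR 0.6), truncated at zero. Meteorology: seasonal temperature and humidity
  with Gaussian noise, gamma-distributed wind.
* **Lockdown suppression.** From the lockdown date the series is multiplied
  by (1 − sᵢ). The station fraction sᵢ is tied to the six standardized
  fragmentation covariates zᵢ: logit(sᵢ) = logit(base) + βᵀzᵢ (default), or
  sᵢ = base·exp(βᵀzᵢ) capped at 0.95 with `suppression_link="log"`. The log
  link keeps log sᵢ exactly linear in the covariates — the natural choice
  when the downstream model is itself log-linked, since the logit link's
  log-scale slope (1 − s) saturates at high suppression. An optional
  pre-lockdown suppression (`pre_suppression_*`) lets scenarios carry a
  fragmentation signal before the lockdown, which is what makes
  before-vs-during coefficient comparisons meaningful in simulation.
* **Rasters.** Seeded cluster growth on a 64×64 grid of 100 m cells:
  each class receives 1 + round(f·(quota−1)) seed cells and regions grow
  from random frontiers until class quotas (largest-remainder apportionment
  of the class proportions) are met; f = 0 gives one compact block per class
  and f = 1 random scatter. Per-station and per-class fragmentation levels
  are drawn independently and class proportions get mild Dirichlet jitter —
  without this the six covariates collapse onto one latent fragmentation
  axis (VIF ≫ 10) and per-covariate effects are unidentifiable.
* **Controls.** Pollutants and population are log-normal (strictly positive,
  right-tailed); temperature, humidity and wind are evaluation-window means
  of the station's meteorology. A standardized suppression signal loads
  mildly (0.1–0.2 on the log scale) on the pollutant columns so that
  confounder adjustment is genuinely exercised.

**What the generator does not emulate:** spatial autocorrelation between
stations, realistic geography or projections, measurement error and
instrument drift, missing-data patterns, pollutant chemistry (controls are
statistically, not mechanistically, linked), and the vector-polygon land-use
structure of real products. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
generative law, not the field validity of the original data analysis.

## The constructed mediated-impact scenario

The end-to-end amplification test uses a scenario designed for
identifiability at a small station count: 20 stations, two-year history,
low noise (innovation SD 0.35 µg/m³, AR 0.2), flat seasonality (annual
amplitude 2, weekly 1), wide fragmentation spread (0.05–0.95), log
suppression link, bases 0.10 before / 0.15 during, standardized-scale
effects (−0.30, 0.27, 0.27, −0.30, −0.45, −0.45) amplified ×1.5 during the
lockdown with the public-ED effect attenuated ×0.5. The flat seasonality
matters because, with a steep counterfactual trend, unconstrained warping
can absorb part of a multiplicative suppression by sliding along the trend,
and it does so more at high suppression — a concavity that systematically
compresses the during-lockdown coefficients. The AI and NP effects are set
larger than the rest because those two covariates are strongly negatively
correlated in raster landscapes (more patches ⇢ less aggregation), so their
same-signed effects nearly cancel in the suppression signal and each is
identified only through its partial variation. The mediated comparison uses
the fragmentation-only UFB/UFD pair because 20 stations cannot support the
ten control smooths (the controlled pair is the right comparison at the
full 145-station scale).

## Numerical notes

* DTW accumulates squared differences and takes one square root at the end;
  the enumeration oracle (`dtw_bruteforce`) walks every admissible path for
  length products ≤ 36 and must agree to 1e-12.
* SARIMAX fits use trend "c" when d + D = 0 and no trend otherwise; constant
  exogenous columns are dropped (they duplicate the level term).
* The GLM/GAM fits retry with start values from an OLS fit to the
  link-transformed response when default IRLS fails; when statsmodels' AIC is
  undefined (tiny effective residual dof) a Gaussian AIC
  n·log(RSS/n) + 2(edf+1) is substituted for smoothing selection.
* Ties in cutoff selection are resolved toward the latest candidate within
  1e-12 of the best mean MOPE.

## Problem sizes used by the test suite and acceptance script

Simulations are sized for a single CPU: the acceptance run uses 24 stations
with a two-year history and 48×48 rasters (cutoff selection over three
candidates, single-order grid (1,0,0)(1,0,0)₇ plus the annual Fourier pair);
the order-recovery check uses 25 replicates of a 420-day SARIMA(1,0,0)(1,0,0)₇
series and a three-order grid; coefficient-recovery and coverage checks use
n = 150 stations with 100 and 200 replicates. These sizes are the package's
own defaults for its verification suite, chosen so the full chain remains
exercised end to end.

## Limitations

* Coefficient CIs are Wald intervals from the penalized covariance; no
  smoothing-selection uncertainty is propagated.
* The DTW statistic is unnormalised, so window length and concentration
  scale enter the score; comparisons are meaningful within a fixed window
  design (as used here), not across designs.
* With an unconstrained warping window, a strong counterfactual trend can
  absorb part of a level suppression (see above); a windowed or
  derivative DTW variant is out of scope.
* The raster generator controls fragmentation only through seed counts;
  it does not reproduce morphological regularities of real cities (road
  networks, zoning contiguity).
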