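# Methods

This note documents the models, algorithms and numerical choices behind
`heatrisk`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Hourly thermal indices

### Relative humidity

Specific humidity q (kg/kg) and surface pressure p give the vapor
pressure through the exact identity e = q·p / (ε + (1−ε)q), ε = 0.622.
Saturation vapor pressure over liquid water uses the Magnus form with the
Alduchov–Eskridge coefficients,

    e_s(T) = 610.94 exp(17.625 T / (243.04 + T))   [Pa, T in °C],

accurate to ~0.4 % over −40…50 °C. RH = 100·e/e_s, clipped to [0, 100]
(supersaturated input reports 100 %). The coefficients are an
implementation choice pinned by oracle tests; any standard Magnus variant
agrees to well under 1 % RH in the relevant range.

### NWS heat index

The operational procedure: the Steadman simple formula
0.5·(T + 61 + 1.2(T − 68) + 0.094·RH) — itself an average of T with a
simple apparent temperature — is used below the 80 °F switchover; at or
above it, the Rothfusz multiple regression applies, minus the low-humidity
adjustment (RH < 13 %, T 80–112 °F) or plus the high-humidity adjustment
(RH > 85 %, T 80–87 °F). Tests pin the implementation to an independently
coded transcription of the published coefficients on a 50-point grid.

### Liljegren outdoor WBGT

Globe and natural wet-bulb temperatures solve steady-state energy
balances for the standard instruments:

- **Globe** (0.0508 m diameter, emissivity 0.95, albedo 0.05): absorbed
  direct/diffuse solar and thermal radiation from sky and ground balance
  convective exchange (sphere correlation Nu = 2 + 0.6 Re^½ Pr^⅓) and
  emission. Sky emissivity is 0.575·e^{1/7} (e in hPa), **capped at 1**:
  the empirical fit exceeds unity above ~49 hPa vapor pressure, which
  would unphysically push equilibrium temperatures above the air
  temperature in saturated heat.
- **Wick** (7 mm × 25.4 mm, emissivity 0.95, albedo 0.4): convection
  (cylinder correlation Nu = 0.281 Re^0.6 Pr^0.44), absorbed radiation and
  evaporative cooling with the heat/mass-transfer analogy ((Pr/Sc)^0.56),
  Sutherland-law air properties and a temperature-linear latent heat.

Both residuals are strictly decreasing in the solved temperature, so the
solver is **vectorized bisection** on the flux residual — deterministic,
bit-for-bit reproducible, and immune to the divergence a raw fixed-point
iteration shows at high wind (where the convective term makes the map
non-contractive). Default bracket widths are ±40/+150 °C (globe) and
−60/+30 °C (wick) around air temperature; the bracket-width tolerance of
1e-4 °C keeps worst-case energy residuals below ~0.05 W m⁻², i.e. under
10⁻³ of the σT⁴ flux scale even where the evaporation term is steepest
(hot, humid air). The iteration cap (default 100) can only be hit with a
violated bracket, which raises a convergence error carrying the residual
(or flags the row as missing under the `flag` policy). Wind speed is
floored at 0.1 m/s to keep the convective correlations defined.

Solar irradiance is split into direct and diffuse parts by the clearness
index: star = S / (S₀ cos z) capped at 0.85,
f_dir = exp(3 − 1.34·star − 1.65/star) clipped to [0, 0.9], with
everything diffuse within 0.5° of the horizon. Zenith angles come from
the NOAA low-accuracy solar-position algorithm using each site's
latitude, longitude and standard-time UTC offset. If coordinates are not
supplied, all irradiance is treated as diffuse and a warning is issued —
adequate for overcast or low-sun hours, biased low for clear middays.

WBGT = 0.7 T_nwb + 0.2 T_g + 0.1 T_a. Physics is computed in SI/°C; heat
index and WBGT are reported in °F at the aggregation boundary because the
downstream index thresholds are defined in °F.

## Annual indices

Days are bounded by local standard time (no daylight-saving shifts),
since 24-hour means are meant to capture overnight minima. A day needs at
least ceil(0.9·24) = 22 hours to enter mean statistics; hour-count
statistics use every available hour because they are sums, not means.
All threshold comparisons are strict (">"): ties at a threshold do not
count. The day-of-year climatology (default baseline 1990–2019) keys
Feb 29 separately using leap years only and raises when any calendar day
has fewer than two baseline years (sample SD undefined). No smoothing is
applied across adjacent calendar days; with ~30 baseline years the
day-level SD is noisy but unbiased, and the days-above-1-SD index is
defined relative to exactly this unsmoothed baseline. When a baseline
day's SD is 0 (constant history), the strict rule degenerates to "days
strictly above the mean". Relative indices use daily-mean (not
daily-max) anomalies.

The catalogue holds 30 indices: for each of temperature, heat index and
WBGT — mean of daily means and mean of daily maxima for full year and
heat season (May 1 – Sep 30 inclusive), two full-year hour-count
thresholds (90/100, 90/105, 85/90 °F respectively), and mean anomaly plus
days-above-1-SD for both windows.

## Outcome panel

Rates are per 1,000 persons per year; combined rates pool counts and
populations before dividing; burden is the HSI share of all documented
encounters (%). Linear time trends are OLS with the two-sided t-test on
n−2 degrees of freedom. Outcome types carry fixed valid year spans
(ambulatory 1998–2018, hospitalization 1991–2018, reportable 1995–2018);
earlier years reflect incomplete reporting and are rejected or warned
about at the file-reading boundary rather than re-derived, because the
underlying completeness indicators are not available to the package.

## Rate model and block bootstrap

The NB2 model (variance μ + αμ²) with log link, installation indicators
and log-population offset is fit by an in-package Newton maximum-
likelihood routine: a damped Newton step on the coefficients alternates
with a 1-D Newton step on log α, both from analytic derivatives, warm-
started from the observed fit inside the bootstrap. The routine matches
the statsmodels NB2 MLE to ~1e-4 in all parameters (pinned by tests) at
roughly an eighth of the cost, which is what makes 2,000-replicate
bootstraps and coverage experiments tractable. The reference
installation (default: lowest total count) has its indicator fixed at 0.
Replicates that fail to converge are dropped and counted (never imputed);
more than 20 % failures adds a warning to the result, 100 % raises.

Bootstrap design choices:

- **Blocks are consecutive calendar years**, drawn with any start index
  (overlapping-block convention) with replacement; ceil(T/L) blocks are
  concatenated, overshooting by up to L−1 years when L does not divide T,
  and never trimmed — blocks stay intact.
- **One resampled year sequence is shared by all installations.** The
  confounder being controlled (secular trend in care-seeking, coding,
  fitness) is common across sites; resampling per site would destroy the
  cross-sectional structure the installation indicators rely on.
- **Dispersion is re-estimated inside every replicate** (full-pipeline
  resampling).
- **Seed protocol:** one master seed spawns independent per-replicate
  substreams (`numpy` SeedSequence), so results are reproducible and
  independent of execution order; with L = 1 the procedure reduces
  exactly to the simple single-observation bootstrap under the same
  protocol, and with L = T every replicate equals the observed fit and
  all intervals collapse to the point estimate.
- **Quantiles are type-7** (linear interpolation), used consistently in
  basic, percentile and BCa intervals.
- **Intervals are formed on the β (log) scale and exponentiated**, where
  the replicate distribution is closer to symmetric.
- BCa: z₀ from the share of replicates below the observed β₁
  (undefined — and raised — if all replicates fall on one side);
  acceleration from the jackknife skewness with **year blocks as the
  deletion units**, matching the bootstrap's dependence structure. A
  replicate distribution collapsed onto the observed value short-circuits
  to the degenerate point interval.

The sensitivity suite fits five variants under a shared seed: plain NB
(Wald CI from the observed information in (β, log α) coordinates), NB
plus a centered linear calendar-year term, and 1-, 2- and 3-year block
bootstraps. The centered year term is a deliberate reading of "a year
term": centering leaves the exposure coefficient's meaning unchanged
while decorrelating it from the intercept.

Projection: projected = round(baseline × RR^Δ), rounding half away from
zero; negative Δ models cooling scenarios.

## Synthetic data

The generator's defaults define the study conditions used throughout the
tests: 10 installations whose full-year mean temperatures span ~56–69 °F
(heat-season means ~73–84 °F) and populations 2,000–45,000 — magnitudes
echoing published installation-level summaries, not assertions about any
real site. Hourly temperature is

    annual mean + seasonal harmonic (peak mid-July)
    + diurnal harmonic (peak ~15:00) + linear trend (0.4–0.5 °F/decade)
    + per-year offset (SD 1.1 °F) + AR(1) noise (φ = 0.95, SD ~2.5–3 °F).

The per-year offset is essential: hourly AR(1) noise alone averages to an
annual-mean spread of only ~0.3 °F, several times smaller than observed
interannual variability (~1–2 °F), which would leave the exposure
coefficient weakly identified in any single simulated study. Humidity is
back-computed from a noisy target RH, pressure is near-constant, wind is
log-normal, and solar follows the clear-sky zenith curve times a Beta
cloudiness factor. For inference-only experiments,
`gen_annual_exposure` draws the annual index directly (site heat-season
mean + trend + N(0, 1.3 °F)), skipping the hourly physics.

Outcome counts are NB2 draws with mean pop·exp(β₀ + β₁·index + γ_site);
β₀ is calibrated so the reference site's rate is 4 per 1,000 at a typical
heat-season mean, keeping counts in a surveillance-like range for any
rate ratio. All-cause counts add a Poisson background of 0.5 encounters
per person-year, which keeps HSI burden in the sub-percent to percent
range. Optional knobs inject a shared exposure trend and a log-linear
outcome year trend for confounding/attenuation experiments.

What the synthetic world does **not** emulate: spatial correlation
between sites, synoptic weather and heat waves, humidity–temperature
dependence beyond the RH target, population turnover, demographic
covariates, and reporting-system changes. Passing tests therefore
demonstrate the correctness and calibration of the *machinery* (index
physics, aggregation logic, NB/bootstrap inference) under the assumed
generative model — not that the assumed model describes any particular
real dataset.

## Problem sizes and runtimes

The test suite runs a 3-site × 8-year hourly world through the full
physics for aggregation tests, and 10-site × 28-year annual-scale panels
for inference. The parameter-recovery check uses 200 simulated studies
with 500 bootstrap replicates each (~2 minutes); the attenuation check
uses 100 simulated studies without bootstrap. The acceptance script runs
one complete 10-site × 28-year hourly pipeline with 2,000-replicate
bootstraps plus the same recovery experiment (~2.5 minutes). These sizes
were chosen so that Monte-Carlo error is small relative to the tolerances
being checked (e.g. binomial SE of a 95 % coverage estimate at n = 200 is
~1.5 %).

## Known limitations

- The hour-count indices are extremely skewed at cool sites (often all
  zero), in which case the rate model for that index is singular; the
  pipeline records the failure for that index and continues.
- The day-boundary convention (local standard time) and the unsmoothed
  climatology are choices; alternatives (UTC days, smoothed normals)
  would shift index values slightly.
- Basic bootstrap intervals can exclude the point estimate under strong
  skew; this is a property of the method, not a defect.
- Coverage of the 2-year block bootstrap at T = 28 years sits a few
  points below nominal (~90–93 % empirically) — the familiar small-T
  undercoverage of block bootstraps, visible and quantified in the
  recovery experiment.
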