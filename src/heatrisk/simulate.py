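"""Synthetic meteorology and outcome panels with known ground truth.

The real analysis rests on two data sources that cannot ship with the
package: gridded hourly meteorology and a restricted military health
surveillance extract. This module generates statistical stand-ins for both
so that every pipeline stage — index derivation, aggregation, model fitting
and bootstrap inference — can be exercised end to end with a known answer.

The default synthetic world has ten installations whose full-year mean
temperatures span roughly 56-69 °F (heat-season means 73-84 °F) and whose
active-duty populations span roughly 2,000-45,000, echoing the magnitudes
of the real installations without asserting anything about them. Hourly
temperature is a seasonal harmonic (peak mid-July) plus a diurnal harmonic
(peak mid-afternoon), a linear warming trend, and AR(1) noise; humidity,
pressure, wind and solar are generated consistently around it. Outcome
counts are NB2 draws whose log rate is linear in an annual heat index with
installation intercepts and a population offset — the same generative form
the fitted model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import met
from .exceptions import InvalidInputError

__all__ = [
    "SiteConfig",
    "TruthRecord",
    "RecoverySummary",
    "default_sites",
    "default_truth",
    "gen_hourly_met",
    "gen_annual_exposure",
    "gen_outcome_panel",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SiteConfig:
    """Climate and population parameters for one synthetic installation."""

    location_id: str
    latitude: float               # degrees north
    longitude: float              # degrees east (negative in CONUS)
    utc_offset: float             # hours, local standard time
    annual_mean: float            # °F
    seasonal_amplitude: float     # °F, half peak-to-trough of the annual cycle
    diurnal_amplitude: float      # °F, half peak-to-trough of the daily cycle
    trend: float                  # °F per decade
    ar1_coeff: float              # hourly noise autocorrelation, |.| < 1
    noise_sd: float               # stationary SD of the hourly noise, °F
    rh_base: float                # mean relative humidity, %
    population: int               # active-duty population (held constant)
    interannual_sd: float = 1.1   # SD of the per-year temperature offset, °F

    def __post_init__(self):
        if not 0 <= abs(self.ar1_coeff) < 1:
            raise InvalidInputError("|ar1_coeff| must be < 1")
        if min(self.seasonal_amplitude, self.diurnal_amplitude,
               self.noise_sd) < 0:
            raise InvalidInputError("amplitudes and noise SD must be >= 0")

    def population_by_year(self, years) -> dict[int, int]:
        return {int(y): self.population for y in years}


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth regression parameters behind a synthetic panel."""

    beta0: float
    beta1_per_unit: float
    gamma: dict[str, float]       # per-location intercept shifts; ref = 0
    dispersion: float             # NB2 alpha
    index_label: str = "temperature_mean_hs"


@dataclass
class RecoverySummary:
    """Aggregate performance of the fit + bootstrap machinery."""

    n_sims: int
    n_failed: int
    mean_beta1: float
    bias: float
    rmse: float
    mean_rr: float
    coverage: float               # fraction of CIs containing the true RR
    coverage_se: float | None     # undefined (None) when n_sims < 2


def default_sites(n_sites: int = 10) -> list[SiteConfig]:
    """Ten synthetic CONUS-like installations spanning warm to hot climates."""
    base = [
        # id        lat    lon     utc  mean  seas  diur trend ar1  sd   rh   pop
        ("site_01", 31.8, -106.4, -7.0, 65.7, 14.5, 10.5, 0.5, 0.95, 2.8, 35.0, 2600),
        ("site_02", 32.4, -84.9, -5.0, 66.3, 13.0, 8.0, 0.4, 0.95, 2.6, 68.0, 21000),
        ("site_03", 35.1, -79.0, -5.0, 62.5, 14.5, 8.5, 0.4, 0.95, 2.7, 65.0, 45000),
        ("site_04", 36.7, -87.5, -6.0, 59.0, 15.5, 9.0, 0.5, 0.95, 2.9, 66.0, 28000),
        ("site_05", 31.1, -97.8, -6.0, 69.4, 14.0, 9.5, 0.5, 0.95, 2.8, 60.0, 41000),
        ("site_06", 34.0, -81.0, -5.0, 63.6, 14.0, 8.5, 0.4, 0.95, 2.6, 67.0, 9500),
        ("site_07", 37.7, -92.1, -6.0, 56.5, 16.0, 9.5, 0.5, 0.95, 3.0, 65.0, 9600),
        ("site_08", 31.0, -93.2, -6.0, 67.1, 13.0, 8.5, 0.4, 0.95, 2.6, 72.0, 8100),
        ("site_09", 39.1, -96.8, -6.0, 55.9, 16.5, 10.0, 0.5, 0.95, 3.1, 62.0, 14800),
        ("site_10", 31.9, -81.6, -5.0, 67.8, 12.5, 8.0, 0.4, 0.95, 2.5, 70.0, 16500),
    ]
    return [SiteConfig(*row) for row in base[:n_sites]]


def default_truth(sites: list[SiteConfig],
                  rr_per_degree: float = 1.15,
                  dispersion: float = 0.3,
                  reference_rate: float = 0.004,
                  reference_exposure: float = 78.0,
                  gamma_spread: float = 1.5,
                  seed: int = 7) -> TruthRecord:
    """A plausible ground truth: RR per °F, NB2 dispersion, site effects.

    The first site is the reference (gamma = 0); the rest draw fixed
    effects from a seeded normal (mean +2 log-units, echoing how the real
    reference installation has by far the lowest counts). ``beta0`` is
    calibrated so the reference site's rate is ``reference_rate`` per
    person-year at a typical heat-season mean of ``reference_exposure`` °F,
    keeping counts in a surveillance-like range for any rate ratio.
    """
    rng = np.random.default_rng(seed)
    gamma = {s.location_id: 0.0 for s in sites[:1]}
    for s in sites[1:]:
        gamma[s.location_id] = float(rng.normal(2.0, gamma_spread / 2.0))
    beta1 = float(np.log(rr_per_degree))
    return TruthRecord(
        beta0=float(np.log(reference_rate) - beta1 * reference_exposure),
        beta1_per_unit=beta1,
        gamma=gamma,
        dispersion=dispersion,
    )


def gen_hourly_met(sites: list[SiteConfig], years, seed: int) -> pd.DataFrame:
    """Hourly meteorology for each site over a span of calendar years.

    Temperature (°F, converted to °C on output) follows
    annual_mean + seasonal + diurnal harmonics + trend + a per-year offset
    (interannual variability, without which year-to-year spread of annual
    means would be unrealistically small) + AR(1) noise.
    Specific humidity is back-computed from a noisy target RH; pressure is
    near-constant; wind is log-normal; solar follows the clear-sky zenith
    curve scaled by a stochastic cloudiness factor. Identical seeds yield
    identical output.
    """
    years = list(years)
    if len(years) == 0:
        raise InvalidInputError("empty year range")
    rng = np.random.default_rng(seed)
    y0, y1 = min(years), max(years)
    ts = pd.date_range(f"{y0}-01-01", f"{y1}-12-31 23:00", freq="h")
    ts = ts[np.isin(ts.year, years)]
    n = len(ts)
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = ts.hour.to_numpy(dtype=float)
    year_frac = ts.year.to_numpy(dtype=float) + (doy - 1) / 365.25

    frames = []
    for s in sites:
        seasonal = s.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - 197.0) / 365.25
        )
        diurnal = s.diurnal_amplitude * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
        trend = s.trend / 10.0 * (year_frac - float(y0))
        year_offset = pd.Series(
            rng.normal(0.0, s.interannual_sd, len(years)), index=years
        )
        annual_anom = year_offset.reindex(ts.year).to_numpy()
        innov_sd = s.noise_sd * np.sqrt(1.0 - s.ar1_coeff ** 2)
        eps = rng.normal(0.0, innov_sd, n)
        phi = s.ar1_coeff
        acc0 = rng.normal(0.0, s.noise_sd)  # stationary start
        noise = signal.lfilter([1.0], [1.0, -phi], eps, zi=[phi * acc0])[0]
        t_f = s.annual_mean + seasonal + diurnal + trend + annual_anom + noise
        t_c = met.f_to_c(t_f)

        rh = np.clip(s.rh_base + rng.normal(0.0, 10.0, n), 5.0, 100.0)
        pressure = 97000.0 + rng.normal(0.0, 250.0, n)
        e = rh / 100.0 * met.saturation_vapor_pressure(t_c)
        q = met.EPSILON * e / (pressure - (1.0 - met.EPSILON) * e)
        wind = rng.lognormal(0.4, 0.6, n)

        zen = met.solar_zenith(ts, s.latitude, s.longitude, s.utc_offset)
        cza = np.maximum(np.cos(zen), 0.0)
        clear = 1000.0 * cza ** 1.15
        cloud = rng.beta(5.0, 2.0, n)       # mean ~0.71 transmission
        solar = clear * cloud

        frames.append(pd.DataFrame({
            "location_id": s.location_id,
            "timestamp": ts,
            "t_air_c": t_c,
            "q_kgkg": q,
            "pressure_pa": pressure,
            "wind_ms": wind,
            "solar_wm2": solar,
        }))
    return pd.concat(frames, ignore_index=True)


def gen_annual_exposure(sites: list[SiteConfig], years, seed: int,
                        year_sd: float = 1.3,
                        shared_trend: float = 0.0) -> pd.DataFrame:
    """Annual heat-index values drawn directly at the annual scale.

    A lightweight alternative to running the full hourly pipeline when only
    the inference machinery is being exercised: each site-year value is the
    site's heat-season mean (annual mean + ~0.8 seasonal amplitude) plus
    its decadal trend, an optional extra shared trend (°F/decade, for
    confounding experiments), and i.i.d. year-to-year noise with SD
    ``year_sd`` (°F, matching the observed spread of heat-season means).
    """
    years = np.asarray(sorted(years))
    rng = np.random.default_rng(seed)
    rows = []
    for s in sites:
        base = s.annual_mean + 0.8 * s.seasonal_amplitude
        tr = (s.trend + shared_trend) / 10.0 * (years - years[0])
        vals = base + tr + rng.normal(0.0, year_sd, len(years))
        rows.append(pd.DataFrame({
            "location_id": s.location_id, "year": years, "value": vals,
        }))
    return pd.concat(rows, ignore_index=True)


def gen_outcome_panel(exposure: pd.DataFrame, truth: TruthRecord,
                      populations: dict[str, int], seed: int,
                      outcome_type: str = "ambulatory",
                      background_rate: float = 0.5,
                      year_log_trend: float = 0.0) -> pd.DataFrame:
    """NB2 outcome counts for every exposure row.

    hsi_count ~ NB2(mu, alpha) with
    mu = population * exp(beta0 + beta1 * value + gamma_loc
    [+ year_log_trend * (year - first year)]); the optional log-linear year
    term injects a secular outcome trend for confounding experiments.
    all_count adds a Poisson background of all-cause encounters
    (``background_rate`` per person-year), which keeps the HSI burden in
    the sub-percent to percent range.
    """
    need = {"location_id", "year", "value"}
    if not need.issubset(exposure.columns):
        raise InvalidInputError(f"exposure needs columns {sorted(need)}")
    missing = set(exposure["location_id"].unique()) - set(populations)
    if missing:
        raise InvalidInputError(f"no population for location(s) {sorted(missing)}")
    rng = np.random.default_rng(seed)
    loc = exposure["location_id"].to_numpy()
    yr = exposure["year"].to_numpy()
    x = exposure["value"].to_numpy(dtype=float)
    pop = np.array([populations[l] for l in loc], dtype=float)
    gam = np.array([truth.gamma.get(l, 0.0) for l in loc])
    eta = (truth.beta0 + truth.beta1_per_unit * x + gam
           + year_log_trend * (yr - yr.min()))
    mu = pop * np.exp(eta)
    if truth.dispersion > 0:
        lam = rng.gamma(1.0 / truth.dispersion, truth.dispersion * mu)
    else:
        lam = mu
    hsi = rng.poisson(lam)
    background = rng.poisson(background_rate * pop)
    return pd.DataFrame({
        "location_id": loc,
        "year": yr,
        "outcome_type": outcome_type,
        "hsi_count": hsi,
        "all_count": hsi + background,
        "population": pop.astype(int),
    })


def recovery_experiment(n_sims: int,
                        sites: list[SiteConfig] | None = None,
                        truth: TruthRecord | None = None,
                        years=range(1991, 2019),
                        n_boot: int = 500,
                        block_len: int = 2,
                        ci_method: str = "basic",
                        seed: int = 0) -> RecoverySummary:
    """Repeated generate -> fit -> bootstrap cycles against known truth.

    Each simulation draws fresh annual exposure and an NB2 panel from
    ``truth``, fits the rate model, and builds a block-bootstrap CI for the
    rate ratio; the summary reports the mean beta1, its bias and RMSE
    against the true coefficient, and the fraction of CIs containing the
    true RR (simulations whose observed fit fails are counted, not
    imputed).
    """
    from .model import ModelSpec, block_bootstrap  # local: avoid cycle

    if n_sims < 1:
        raise InvalidInputError("n_sims must be >= 1")
    sites = default_sites() if sites is None else sites
    truth = default_truth(sites) if truth is None else truth
    pops = {s.location_id: s.population for s in sites}
    years = list(years)
    master = np.random.SeedSequence(seed)
    sim_seeds = master.spawn(n_sims)

    true_rr = float(np.exp(truth.beta1_per_unit))
    betas, covered = [], []
    n_failed = 0
    for child in sim_seeds:
        s_exp, s_pan, s_boot = [
            int(c.generate_state(1, dtype=np.uint64)[0] >> 33)
            for c in child.spawn(3)
        ]
        exposure = gen_annual_exposure(sites, years, seed=s_exp)
        pan = gen_outcome_panel(exposure, truth, pops, seed=s_pan)
        spec = ModelSpec(outcome_type="ambulatory", block_len=block_len,
                         n_boot=n_boot, ci_method=ci_method,
                         reference_location=sites[0].location_id,
                         seed=s_boot)
        try:
            res = block_bootstrap(pan, exposure, spec)
        except Exception:
            n_failed += 1
            continue
        betas.append(res.observed.beta1)
        covered.append(res.ci_low <= true_rr <= res.ci_high)

    betas = np.asarray(betas)
    n_ok = len(betas)
    if n_ok == 0:
        raise InvalidInputError("every simulation failed; nothing to summarize")
    cov = float(np.mean(covered))
    cov_se = (float(np.sqrt(cov * (1 - cov) / n_ok)) if n_ok >= 2 else None)
    return RecoverySummary(
        n_sims=n_sims,
        n_failed=n_failed,
        mean_beta1=float(betas.mean()),
        bias=float(betas.mean() - truth.beta1_per_unit),
        rmse=float(np.sqrt(np.mean((betas - truth.beta1_per_unit) ** 2))),
        mean_rr=float(np.exp(betas).mean()),
        coverage=cov,
        coverage_se=cov_se,
    )
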