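"""Negative-binomial rate models with block-bootstrap confidence intervals.

The exposure-response model regresses annual HSI counts on one annual heat
index with a log link, installation indicator variables, and the log of the
active-duty population as an offset:

    log E[count_ij / pop_ij] = beta0 + beta1 * index_ij + gamma_j

with the reference installation's gamma fixed at 0 and NB2 over-dispersion
estimated jointly by maximum likelihood. Confidence intervals for the rate
ratio exp(beta1 * increment) come from a block bootstrap that resamples
blocks of consecutive calendar years with replacement — the same resampled
year sequence applied to every installation, preserving the cross-sectional
panel structure while breaking serial dependence. Intervals are formed on
the beta (log) scale and exponentiated; both basic (empirical) and BCa
variants are provided, plus the non-bootstrap and single-year-bootstrap
sensitivity fits and the forward projection of case burden.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _nb2
from .annual import IndexSpec
from .exceptions import (
    ConvergenceError,
    DataIntegrityError,
    InvalidInputError,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "BootstrapResult",
    "DesignBundle",
    "build_design",
    "fit_negbin",
    "resample_blocks",
    "block_bootstrap",
    "jackknife_beta1",
    "basic_ci",
    "percentile_ci",
    "bca_ci",
    "rate_ratio",
    "sensitivity_suite",
    "project_counts",
    "ProjectionResult",
]


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: exposure, outcome, bootstrap scheme.

    ``increment`` is the exposure step the rate ratio refers to (1 °F for
    degree indices, 1 hour or 1 day for count indices).
    """

    index_spec: IndexSpec | None = None
    outcome_type: str = "ambulatory"
    block_len: int = 2
    n_boot: int = 2000
    ci_method: str = "basic"
    alpha: float = 0.05
    reference_location: str | None = None
    seed: int = 0
    increment: float = 1.0

    def __post_init__(self):
        if self.n_boot < 1:
            raise InvalidInputError("n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")
        if self.increment <= 0:
            raise InvalidInputError("increment must be > 0")
        if self.block_len < 1:
            raise InvalidInputError("block_len must be >= 1")
        if self.ci_method not in ("basic", "bca", "percentile"):
            raise InvalidInputError(f"unknown ci_method '{self.ci_method}'")


@dataclass
class DesignBundle:
    """Materialized regression inputs, one row per installation-year."""

    y: np.ndarray                 # counts
    X: np.ndarray                 # intercept, exposure, indicators[, year]
    offset: np.ndarray            # log population
    columns: list[str]
    years: np.ndarray             # per-row calendar year
    locations: np.ndarray         # per-row location id
    unique_years: np.ndarray      # sorted unique years
    reference_location: str

    def rows_for_years(self, year_seq) -> "DesignBundle":
        """Stack the design rows for a resampled year sequence.

        Duplicate years contribute duplicate rows, mirroring how the
        bootstrap assembles a new panel from sampled blocks.
        """
        year_seq = np.asarray(year_seq)
        if len(year_seq) == 0:
            raise InvalidInputError("empty year sequence")
        order = {y: np.flatnonzero(self.years == y) for y in self.unique_years}
        idx = np.concatenate([order[y] for y in year_seq])
        return DesignBundle(
            y=self.y[idx], X=self.X[idx], offset=self.offset[idx],
            columns=self.columns, years=self.years[idx],
            locations=self.locations[idx], unique_years=self.unique_years,
            reference_location=self.reference_location,
        )


@dataclass(frozen=True)
class FitResult:
    """Fitted coefficients of one NB2 rate model."""

    beta0: float
    beta1: float
    gamma: dict[str, float]       # per-location effects; reference fixed at 0
    dispersion: float
    converged: bool
    log_likelihood: float
    params: np.ndarray = field(repr=False)


@dataclass
class BootstrapResult:
    """Observed fit plus the bootstrap replicate distribution and CI."""

    observed: FitResult
    replicates: np.ndarray        # beta1 values from converged replicates
    n_failed: int
    rr: float                     # exp(observed beta1 * increment)
    rr_boot_mean: float           # exp(mean replicate beta1 * increment)
    ci_low: float
    ci_high: float
    method: str
    spec: ModelSpec
    warnings: list[str] = field(default_factory=list)


def build_design(panel: pd.DataFrame, exposure: pd.DataFrame,
                 spec: ModelSpec) -> DesignBundle:
    """Join the outcome panel to exposure values and build the design matrix.

    ``exposure`` needs columns (location_id, year, value); ``panel`` is one
    outcome type's rows. Indicator columns are created for every location
    except the reference (default: the location with the smallest total HSI
    count, following the lowest-count reference convention).
    """
    pan = panel[panel["outcome_type"] == spec.outcome_type] \
        if "outcome_type" in panel.columns else panel
    if len(pan) == 0:
        raise InvalidInputError(
            f"panel has no rows for outcome type '{spec.outcome_type}'"
        )
    if pan.duplicated(subset=["location_id", "year"]).any():
        raise DataIntegrityError("duplicate (location, year) rows in panel")
    if exposure.duplicated(subset=["location_id", "year"]).any():
        raise DataIntegrityError("duplicate (location, year) rows in exposure")
    merged = pan.merge(
        exposure[["location_id", "year", "value"]],
        on=["location_id", "year"], how="left", validate="one_to_one",
    )
    if merged["value"].isna().any():
        bad = merged[merged["value"].isna()][["location_id", "year"]]
        keys = [tuple(r) for r in bad.itertuples(index=False)][:5]
        raise InvalidInputError(
            f"exposure missing for panel keys (first few): {keys}"
        )
    locs = np.sort(merged["location_id"].unique())
    ref = spec.reference_location
    if ref is None:
        totals = merged.groupby("location_id")["hsi_count"].sum()
        ref = str(totals.idxmin())
    elif ref not in locs:
        raise InvalidInputError(f"reference location '{ref}' absent from panel")
    others = [l for l in locs if l != ref]
    n = len(merged)
    X = np.ones((n, 2 + len(others)))
    X[:, 1] = merged["value"].to_numpy(dtype=float)
    loc_arr = merged["location_id"].to_numpy()
    for j, l in enumerate(others):
        X[:, 2 + j] = (loc_arr == l).astype(float)
    return DesignBundle(
        y=merged["hsi_count"].to_numpy(dtype=float),
        X=X,
        offset=np.log(merged["population"].to_numpy(dtype=float)),
        columns=["intercept", "exposure"] + [f"loc[{l}]" for l in others],
        years=merged["year"].to_numpy(),
        locations=loc_arr,
        unique_years=np.sort(merged["year"].unique()),
        reference_location=ref,
    )


def fit_negbin(design: DesignBundle,
               start_params: np.ndarray | None = None) -> FitResult:
    """Fit the NB2 model by maximum likelihood (dispersion jointly).

    Non-convergence is flagged on the result rather than raised, so
    bootstrap replicates can tolerate occasional failures; a failed linear
    solve returns a flagged result with NaN coefficients.
    """
    if np.all(design.y == 0):
        raise InvalidInputError("all-zero response: rate model undefined")
    if len(design.y) <= design.X.shape[1]:
        raise InvalidInputError(
            "need more rows than design columns "
            f"({len(design.y)} rows, {design.X.shape[1]} columns)"
        )
    res = _nb2.fit_nb2(design.y, design.X, design.offset, start=start_params)
    if res.params is None:
        nanp = np.full(design.X.shape[1] + 1, np.nan)
        return FitResult(np.nan, np.nan, {}, np.nan, False, -np.inf, nanp)
    gamma = {design.reference_location: 0.0}
    for name, value in zip(design.columns[2:], res.params[2:-1]):
        gamma[name[4:-1]] = float(value)
    return FitResult(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        gamma=gamma,
        dispersion=float(res.params[-1]),
        converged=bool(res.converged),
        log_likelihood=res.loglik,
        params=res.params,
    )


def resample_blocks(years, block_len: int, rng) -> np.ndarray:
    """Resample a year series as blocks of consecutive years.

    Draws ceil(T / L) block start positions uniformly (any start index, so
    blocks may overlap across draws) with replacement and concatenates the
    blocks. When L does not divide T the result overshoots the original
    length by up to L - 1 years and is kept untrimmed, matching an
    "approximate length" convention that never breaks blocks.
    """
    years = np.asarray(sorted(years))
    t = len(years)
    if block_len > t:
        raise InvalidInputError(
            f"block length {block_len} exceeds series length {t}"
        )
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_blocks = math.ceil(t / block_len)
    starts = rng.integers(0, t - block_len + 1, size=n_blocks)
    return np.concatenate([years[s:s + block_len] for s in starts])


def _quantile(x, q):
    """Type-7 (linear interpolation) empirical quantile, the documented rule."""
    return np.quantile(np.asarray(x, dtype=float), q, method="linear")


def basic_ci(replicates, observed_stat: float, alpha: float = 0.05):
    """Basic (empirical) bootstrap interval: 2 theta-hat - Q(1 - a/2, a/2)."""
    reps = np.asarray(replicates, dtype=float)
    if len(reps) < 2:
        raise InvalidInputError("basic_ci requires at least 2 replicates")
    lo = 2.0 * observed_stat - _quantile(reps, 1.0 - alpha / 2.0)
    hi = 2.0 * observed_stat - _quantile(reps, alpha / 2.0)
    return float(lo), float(hi)


def percentile_ci(replicates, alpha: float = 0.05):
    """Percentile bootstrap interval from the replicate distribution."""
    reps = np.asarray(replicates, dtype=float)
    if len(reps) < 2:
        raise InvalidInputError("percentile_ci requires at least 2 replicates")
    return (
        float(_quantile(reps, alpha / 2.0)),
        float(_quantile(reps, 1.0 - alpha / 2.0)),
    )


def bca_ci(replicates, observed_stat: float, jackknife_stats,
           alpha: float = 0.05):
    """Bias-corrected and accelerated bootstrap interval.

    z0 comes from the share of replicates below the observed statistic and
    the acceleration from the jackknife skewness (leave-one-block-out
    statistics). A replicate distribution collapsed onto the observed value
    yields the degenerate point interval; replicates entirely on one side
    of the observed statistic leave z0 undefined and raise.
    """
    reps = np.asarray(replicates, dtype=float)
    jack = np.asarray(jackknife_stats, dtype=float)
    if len(reps) < 2:
        raise InvalidInputError("bca_ci requires at least 2 replicates")
    if np.allclose(reps, observed_stat):
        return float(observed_stat), float(observed_stat)
    prop = np.mean(reps < observed_stat)
    if prop == 0.0 or prop == 1.0:
        raise InvalidInputError(
            "all bootstrap replicates fall on one side of the observed "
            f"statistic (proportion below = {prop:.0f}); z0 is undefined"
        )
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = 0.0 if den == 0 else num / den
    zlo = stats.norm.ppf(alpha / 2.0)
    zhi = stats.norm.ppf(1.0 - alpha / 2.0)
    a1 = stats.norm.cdf(z0 + (z0 + zlo) / (1.0 - a * (z0 + zlo)))
    a2 = stats.norm.cdf(z0 + (z0 + zhi) / (1.0 - a * (z0 + zhi)))
    return float(_quantile(reps, a1)), float(_quantile(reps, a2))


def rate_ratio(beta1: float, increment: float = 1.0) -> float:
    """Multiplicative rate change per ``increment`` units of exposure."""
    if increment <= 0:
        raise InvalidInputError("increment must be > 0")
    return float(np.exp(beta1 * increment))


def jackknife_beta1(design: DesignBundle, spec: ModelSpec,
                    start_params: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-block-out beta1 estimates (deletion units = year blocks).

    Years are partitioned into consecutive blocks of ``spec.block_len``
    (the final block may be shorter); each block is deleted in turn and the
    model refit.
    """
    years = design.unique_years
    blocks = [
        years[i:i + spec.block_len]
        for i in range(0, len(years), spec.block_len)
    ]
    out = []
    for blk in blocks:
        keep = years[~np.isin(years, blk)]
        sub = design.rows_for_years(keep)
        fit = fit_negbin(sub, start_params=start_params)
        if fit.converged:
            out.append(fit.beta1)
    if len(out) < 2:
        raise ConvergenceError("too few converged jackknife fits for BCa")
    return np.asarray(out)


def block_bootstrap(panel: pd.DataFrame, exposure: pd.DataFrame,
                    spec: ModelSpec) -> BootstrapResult:
    """Full block-bootstrap analysis of one model specification.

    Fits the observed model, then for each of ``spec.n_boot`` replicates
    draws a resampled year sequence (shared across installations), stacks
    the corresponding panel rows, and refits. The confidence interval is
    built from converged replicate beta1 values on the log scale and
    exponentiated to the rate-ratio scale. Per-replicate random streams are
    spawned from the master seed, so results do not depend on execution
    order.
    """
    design = build_design(panel, exposure, spec)
    observed = fit_negbin(design)
    if not observed.converged:
        raise ConvergenceError("observed fit did not converge")
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_boot)
    reps = []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        year_seq = resample_blocks(design.unique_years, spec.block_len, rng)
        fit = fit_negbin(design.rows_for_years(year_seq),
                         start_params=observed.params)
        if fit.converged and np.isfinite(fit.beta1):
            reps.append(fit.beta1)
        else:
            n_failed += 1
    notes = []
    if n_failed == spec.n_boot:
        raise ConvergenceError("every bootstrap replicate failed to converge")
    if n_failed > 0.2 * spec.n_boot:
        msg = f"{n_failed}/{spec.n_boot} bootstrap replicates failed"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    reps = np.asarray(reps)

    if spec.ci_method == "basic":
        lo, hi = basic_ci(reps, observed.beta1, spec.alpha)
    elif spec.ci_method == "percentile":
        lo, hi = percentile_ci(reps, spec.alpha)
    elif np.allclose(reps, observed.beta1):
        # degenerate replicate set (e.g. block_len = T): the interval
        # collapses before any jackknife is needed
        lo = hi = observed.beta1
    else:
        jack = jackknife_beta1(design, spec, start_params=observed.params)
        lo, hi = bca_ci(reps, observed.beta1, jack, spec.alpha)
    inc = spec.increment
    return BootstrapResult(
        observed=observed,
        replicates=reps,
        n_failed=n_failed,
        rr=rate_ratio(observed.beta1, inc),
        rr_boot_mean=rate_ratio(float(reps.mean()), inc),
        ci_low=rate_ratio(lo, inc),
        ci_high=rate_ratio(hi, inc),
        method=spec.ci_method,
        spec=spec,
        warnings=notes,
    )


def _wald_row(design: DesignBundle, spec: ModelSpec, with_year: bool):
    """Non-bootstrap NB fit with a Wald CI, optionally with a year term."""
    if with_year:
        yr = design.years.astype(float)
        Xy = np.column_stack([design.X, yr - yr.mean()])
        design = DesignBundle(
            y=design.y, X=Xy, offset=design.offset,
            columns=design.columns + ["year_centered"], years=design.years,
            locations=design.locations, unique_years=design.unique_years,
            reference_location=design.reference_location,
        )
    fit = fit_negbin(design)
    if not fit.converged:
        return fit, (np.nan, np.nan)
    info = _nb2.observed_information(
        np.append(fit.params[:-1], fit.params[-1]), design.y, design.X,
        design.offset,
    )
    try:
        cov = np.linalg.inv(info)
        se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        return fit, (np.nan, np.nan)
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return fit, (fit.beta1 - z * se, fit.beta1 + z * se)


def sensitivity_suite(panel: pd.DataFrame, exposure: pd.DataFrame,
                      spec: ModelSpec) -> pd.DataFrame:
    """The five sensitivity variants of one model, one summary row each.

    (a) plain NB fit (Wald CI), (b) NB with a centered linear year term
    (Wald CI), (c) single-year bootstrap, (d) 2-year block bootstrap,
    (e) 3-year block bootstrap — all under the shared seed protocol.
    Variant failures are recorded in the row, not raised.
    """
    design = build_design(panel, exposure, spec)
    inc = spec.increment
    rows = []

    for label, with_year in (("nb_plain", False), ("nb_year_term", True)):
        try:
            fit, (lo, hi) = _wald_row(design, spec, with_year)
            rows.append((label, rate_ratio(fit.beta1, inc),
                         rate_ratio(lo, inc) if np.isfinite(lo) else np.nan,
                         rate_ratio(hi, inc) if np.isfinite(hi) else np.nan,
                         "wald", 0, 0, None))
        except Exception as exc:  # recorded, not raised
            rows.append((label, np.nan, np.nan, np.nan, "wald", 0, 0, str(exc)))

    for label, block_len in (("bootstrap_L1", 1), ("bootstrap_L2", 2),
                             ("bootstrap_L3", 3)):
        try:
            bspec = ModelSpec(
                index_spec=spec.index_spec, outcome_type=spec.outcome_type,
                block_len=block_len, n_boot=spec.n_boot,
                ci_method=spec.ci_method, alpha=spec.alpha,
                reference_location=spec.reference_location, seed=spec.seed,
                increment=spec.increment,
            )
            res = block_bootstrap(panel, exposure, bspec)
            rows.append((label, res.rr, res.ci_low, res.ci_high,
                         res.method, len(res.replicates), res.n_failed, None))
        except Exception as exc:
            rows.append((label, np.nan, np.nan, np.nan, spec.ci_method,
                         0, 0, str(exc)))

    return pd.DataFrame(
        rows,
        columns=["variant", "rr", "ci_low", "ci_high", "method",
                 "n_replicates", "n_failed", "error"],
    )


@dataclass(frozen=True)
class ProjectionResult:
    """Projected annual count under an exposure shift."""

    projected: int
    delta: int


def project_counts(baseline_count: float, rr_per_unit: float,
                   delta_units: float) -> ProjectionResult:
    """Project a baseline annual count under a shift in the exposure index.

    The projected count is baseline * rr ** delta (rounded half away from
    zero); negative shifts model cooling scenarios.
    """
    if baseline_count < 0:
        raise InvalidInputError("baseline_count must be >= 0")
    if rr_per_unit <= 0:
        raise InvalidInputError("rate ratio must be > 0")
    projected = baseline_count * rr_per_unit ** delta_units
    rounded = int(math.floor(projected + 0.5))
    return ProjectionResult(projected=rounded,
                            delta=rounded - int(round(baseline_count)))
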