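"""NB rate model, block bootstrap, CI construction, and projection."""

import numpy as np
import pandas as pd
import pytest

from heatrisk import model, simulate
from heatrisk.exceptions import ConvergenceError, DataIntegrityError, InvalidInputError
from heatrisk.model import ModelSpec


class TestBuildDesign:
    def test_shapes_and_columns(self, panel_world):
        expo, pan = panel_world
        spec = ModelSpec(reference_location="site_01")
        d = model.build_design(pan, expo, spec)
        # 10 locations x 28 years; intercept + exposure + 9 indicators
        assert d.X.shape == (280, 11)
        assert d.columns[:2] == ["intercept", "exposure"]
        assert sum(c.startswith("loc[") for c in d.columns) == 9
        assert d.reference_location == "site_01"

    def test_small_panel_layout(self):
        pan = pd.DataFrame({
            "location_id": ["a", "a", "b", "b", "c", "c"],
            "year": [2000, 2001] * 3,
            "outcome_type": "ambulatory",
            "hsi_count": [1, 2, 3, 4, 5, 6],
            "all_count": 100, "population": 1000,
        })
        expo = pan[["location_id", "year"]].assign(value=70.0)
        d = model.build_design(pan, expo, ModelSpec(reference_location="a"))
        assert d.X.shape == (6, 4)

    def test_default_reference_is_lowest_count_location(self, panel_world):
        expo, pan = panel_world
        d = model.build_design(pan, expo, ModelSpec())
        totals = pan.groupby("location_id")["hsi_count"].sum()
        assert d.reference_location == totals.idxmin()

    def test_duplicate_keys_rejected(self, panel_world):
        expo, pan = panel_world
        dup = pd.concat([pan, pan.iloc[:1]], ignore_index=True)
        with pytest.raises(DataIntegrityError):
            model.build_design(dup, expo, ModelSpec())

    def test_unmatched_join_keys_listed(self, panel_world):
        expo, pan = panel_world
        with pytest.raises(InvalidInputError, match="site_01"):
            model.build_design(
                pan, expo[expo.location_id != "site_01"], ModelSpec()
            )

    def test_absent_reference_rejected(self, panel_world):
        expo, pan = panel_world
        with pytest.raises(InvalidInputError, match="nowhere"):
            model.build_design(
                pan, expo, ModelSpec(reference_location="nowhere")
            )


class TestFitNegbin:
    def test_intercept_only_equals_log_mean_rate(self):
        # counts {2, 4} on population 1000: beta0 -> log(0.003)
        pan = pd.DataFrame({
            "location_id": "a", "year": [2000, 2001],
            "outcome_type": "ambulatory", "hsi_count": [2, 4],
            "all_count": 100, "population": 1000,
        })
        expo = pan[["location_id", "year"]].assign(value=0.0)
        d = model.build_design(pan, expo, ModelSpec(reference_location="a"))
        # drop the exposure column (constant zero) for an intercept-only fit
        d.X = d.X[:, :1]
        d.columns = d.columns[:1]
        fit = model.fit_negbin(d)
        assert fit.beta0 == pytest.approx(np.log(0.003), abs=1e-4)

    def test_recovers_simulation_truth(self, fitted_world, truth10):
        _, fit = fitted_world
        assert fit.converged
        # n=280: loose Monte-Carlo tolerance on each parameter class
        assert fit.beta1 == pytest.approx(truth10.beta1_per_unit, abs=0.05)
        assert fit.dispersion == pytest.approx(truth10.dispersion, rel=0.5)
        assert fit.gamma["site_01"] == 0.0

    def test_matches_statsmodels_mle(self, fitted_world):
        sm = pytest.importorskip("statsmodels.api")
        design, fit = fitted_world
        ref = sm.NegativeBinomial(
            design.y, design.X, offset=design.offset
        ).fit(disp=0, maxiter=200)
        assert np.allclose(fit.params[:-1], ref.params[:-1], atol=2e-4)
        assert fit.dispersion == pytest.approx(ref.params[-1], abs=2e-4)

    def test_poisson_limit(self, sites10):
        # data generated with dispersion 0 -> betas match a Poisson GLM
        sm = pytest.importorskip("statsmodels.api")
        truth = simulate.default_truth(sites10, dispersion=0.0)
        expo = simulate.gen_annual_exposure(sites10, range(1991, 2019), seed=31)
        pops = {s.location_id: s.population for s in sites10}
        pan = simulate.gen_outcome_panel(expo, truth, pops, seed=32)
        d = model.build_design(pan, expo, ModelSpec(reference_location="site_01"))
        fit = model.fit_negbin(d)
        pois = sm.GLM(
            d.y, d.X, family=sm.families.Poisson(), offset=d.offset
        ).fit()
        assert np.allclose(fit.params[:-1], pois.params, atol=1e-3)
        assert fit.dispersion < 0.01

    def test_all_zero_response_rejected(self, panel_world):
        expo, pan = panel_world
        zero = pan.assign(hsi_count=0)
        d = model.build_design(zero, expo, ModelSpec())
        with pytest.raises(InvalidInputError):
            model.fit_negbin(d)

    def test_year_permutation_leaves_fit_unchanged(self, panel_world):
        expo, pan = panel_world
        spec = ModelSpec(reference_location="site_01")
        fit0 = model.fit_negbin(model.build_design(pan, expo, spec))
        rng = np.random.default_rng(3)
        shuffled_years = rng.permutation(sorted(pan.year.unique()))
        order = pd.concat(
            [pan[pan.year == y] for y in shuffled_years], ignore_index=True
        )
        fit1 = model.fit_negbin(model.build_design(order, expo, spec))
        assert np.allclose(fit0.params, fit1.params, atol=1e-9)


class TestResampleBlocks:
    def test_even_division(self, rng):
        out = model.resample_blocks(range(1991, 2019), 2, rng)
        assert len(out) == 28
        # blocks are consecutive pairs
        pairs = out.reshape(-1, 2)
        assert np.all(pairs[:, 1] == pairs[:, 0] + 1)

    def test_odd_length_overshoots_untrimmed(self, rng):
        out = model.resample_blocks(range(1991, 2018), 2, rng)  # T=27
        assert len(out) == 28

    def test_single_year_blocks_degenerate(self, rng):
        out = model.resample_blocks(range(2000, 2010), 1, rng)
        assert len(out) == 10
        assert set(out) <= set(range(2000, 2010))

    def test_block_longer_than_series_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            model.resample_blocks(range(2000, 2003), 5, rng)


class TestBasicCI:
    @staticmethod
    def type7_quantile_oracle(xs, q):
        """Brute-force type-7 quantile from sorted order statistics."""
        xs = sorted(xs)
        h = (len(xs) - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, len(xs) - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    def test_matches_order_statistics_oracle(self):
        reps = [-2.0, -1.0, 0.0, 1.0, 2.0]
        lo, hi = model.basic_ci(reps, observed_stat=0.0, alpha=0.05)
        assert lo == pytest.approx(-self.type7_quantile_oracle(reps, 0.975))
        assert hi == pytest.approx(-self.type7_quantile_oracle(reps, 0.025))

    def test_oracle_agreement_for_all_small_sets(self, rng):
        for n in range(2, 11):
            reps = rng.normal(0, 1, n)
            obs = rng.normal()
            lo, hi = model.basic_ci(reps, obs, alpha=0.1)
            assert lo == pytest.approx(
                2 * obs - self.type7_quantile_oracle(reps, 0.95), abs=1e-12
            )
            assert hi == pytest.approx(
                2 * obs - self.type7_quantile_oracle(reps, 0.05), abs=1e-12
            )

    def test_symmetric_replicates_equal_percentile(self, rng):
        obs = 1.0
        half = rng.normal(0, 1, 500)
        reps = np.concatenate([obs + half, obs - half])  # exactly symmetric
        b_lo, b_hi = model.basic_ci(reps, obs)
        p_lo, p_hi = model.percentile_ci(reps)
        assert b_lo == pytest.approx(p_lo, abs=1e-9)
        assert b_hi == pytest.approx(p_hi, abs=1e-9)

    def test_degenerate_replicates_collapse(self):
        lo, hi = model.basic_ci([0.5] * 10, 0.5)
        assert lo == hi == 0.5

    def test_too_few_replicates(self):
        with pytest.raises(InvalidInputError):
            model.basic_ci([1.0], 1.0)


class TestBCaCI:
    def test_hand_computed_small_set(self):
        from scipy import stats

        reps = np.array([0.8, 0.9, 1.0, 1.1, 1.3, 1.6])
        obs = 1.05
        jack = np.array([0.9, 1.0, 1.1, 1.2])
        alpha = 0.1
        # step-by-step BCa arithmetic
        z0 = stats.norm.ppf(np.mean(reps < obs))        # 4/6 below
        jm = jack.mean()
        a = np.sum((jm - jack) ** 3) / (6 * np.sum((jm - jack) ** 2) ** 1.5)
        zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
        a1 = stats.norm.cdf(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
        a2 = stats.norm.cdf(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
        exp_lo = np.quantile(reps, a1, method="linear")
        exp_hi = np.quantile(reps, a2, method="linear")
        lo, hi = model.bca_ci(reps, obs, jack, alpha=alpha)
        assert lo == pytest.approx(exp_lo, abs=1e-12)
        assert hi == pytest.approx(exp_hi, abs=1e-12)

    def test_symmetric_zero_acceleration_equals_percentile(self, rng):
        obs = 0.0
        half = np.abs(rng.normal(0, 1, 1000))
        reps = np.concatenate([half, -half])            # median exactly at obs
        jack = np.array([-1.0, 1.0, -2.0, 2.0])         # zero skewness
        b = model.bca_ci(reps, obs, jack)
        p = model.percentile_ci(reps)
        assert b[0] == pytest.approx(p[0], abs=1e-9)
        assert b[1] == pytest.approx(p[1], abs=1e-9)

    def test_shift_equivariance(self, rng):
        reps = rng.normal(0, 1, 200)
        jack = rng.normal(0, 1, 10)
        obs = 0.1
        c = 2.5
        lo, hi = model.bca_ci(reps, obs, jack)
        lo2, hi2 = model.bca_ci(reps + c, obs + c, jack + c)
        assert lo2 == pytest.approx(lo + c, abs=1e-9)
        assert hi2 == pytest.approx(hi + c, abs=1e-9)

    def test_one_sided_replicates_raise(self):
        with pytest.raises(InvalidInputError, match="one side"):
            model.bca_ci([1.0, 2.0, 3.0], 0.5, [0.4, 0.5, 0.6])


class TestRateRatio:
    def test_zero_beta_is_unity(self):
        assert model.rate_ratio(0.0) == 1.0

    def test_inverse_of_log(self):
        assert model.rate_ratio(np.log(1.16), 1.0) == pytest.approx(1.16)

    def test_increment_scaling(self):
        b = 0.002
        assert model.rate_ratio(b, 10.0) == pytest.approx(np.exp(0.02))
        assert model.rate_ratio(b, 10.0) > model.rate_ratio(b, 1.0)


class TestBlockBootstrap:
    def test_replicates_plus_failures_account_for_all(self, panel_world):
        expo, pan = panel_world
        res = model.block_bootstrap(
            pan, expo, ModelSpec(n_boot=100, seed=9,
                                 reference_location="site_01")
        )
        assert len(res.replicates) + res.n_failed == 100

    def test_single_year_blocks_match_independent_simple_bootstrap(
            self, panel_world):
        expo, pan = panel_world
        spec = ModelSpec(n_boot=60, seed=14, block_len=1,
                         reference_location="site_01")
        res = model.block_bootstrap(pan, expo, spec)

        # independent re-implementation of simple (single-observation)
        # bootstrap under the same documented seed protocol
        design = model.build_design(pan, expo, spec)
        observed = model.fit_negbin(design)
        years = design.unique_years
        mine = []
        for child in np.random.SeedSequence(14).spawn(60):
            rng = np.random.default_rng(child)
            seq = years[rng.integers(0, len(years), size=len(years))]
            fit = model.fit_negbin(design.rows_for_years(seq),
                                   start_params=observed.params)
            mine.append(fit.beta1)
        assert np.allclose(sorted(res.replicates), sorted(mine), atol=1e-12)

    def test_whole_series_block_collapses_ci(self, panel_world):
        expo, pan = panel_world
        t = pan.year.nunique()
        res = model.block_bootstrap(
            pan, expo, ModelSpec(n_boot=30, seed=3, block_len=t,
                                 reference_location="site_01")
        )
        assert np.allclose(res.replicates, res.observed.beta1)
        assert res.ci_low == pytest.approx(res.rr, rel=1e-9)
        assert res.ci_high == pytest.approx(res.rr, rel=1e-9)

    def test_seed_reproducibility(self, panel_world):
        expo, pan = panel_world
        spec = ModelSpec(n_boot=40, seed=77, reference_location="site_01")
        a = model.block_bootstrap(pan, expo, spec)
        b = model.block_bootstrap(pan, expo, spec)
        assert np.array_equal(a.replicates, b.replicates)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_bca_interval_orders_bounds(self, panel_world):
        expo, pan = panel_world
        res = model.block_bootstrap(
            pan, expo, ModelSpec(n_boot=200, seed=9, ci_method="bca",
                                 reference_location="site_01")
        )
        assert res.ci_low <= res.ci_high


class TestSensitivitySuite:
    def test_five_rows(self, panel_world):
        expo, pan = panel_world
        out = model.sensitivity_suite(
            pan, expo, ModelSpec(n_boot=50, seed=4,
                                 reference_location="site_01")
        )
        assert len(out) == 5
        assert list(out.variant) == ["nb_plain", "nb_year_term",
                                     "bootstrap_L1", "bootstrap_L2",
                                     "bootstrap_L3"]
        assert out.error.isna().all() or (out.error.isnull()).all()

    def test_trend_free_blocks_overlap(self, sites10):
        # L=1 and L=2 bootstrap CIs overlap on data without secular trend
        trend_free = [
            simulate.SiteConfig(
                s.location_id, s.latitude, s.longitude, s.utc_offset,
                s.annual_mean, s.seasonal_amplitude, s.diurnal_amplitude,
                0.0, s.ar1_coeff, s.noise_sd, s.rh_base, s.population,
            )
            for s in sites10
        ]
        truth = simulate.default_truth(trend_free)
        expo = simulate.gen_annual_exposure(trend_free, range(1991, 2019),
                                            seed=41)
        pops = {s.location_id: s.population for s in trend_free}
        pan = simulate.gen_outcome_panel(expo, truth, pops, seed=42)
        out = model.sensitivity_suite(
            pan, expo, ModelSpec(n_boot=200, seed=4,
                                 reference_location="site_01")
        )
        l1 = out[out.variant == "bootstrap_L1"].iloc[0]
        l2 = out[out.variant == "bootstrap_L2"].iloc[0]
        assert max(l1.ci_low, l2.ci_low) <= min(l1.ci_high, l2.ci_high)


class TestProjection:
    def test_reference_projection(self):
        res = model.project_counts(3612, 1.16, 1)
        assert res.projected == 4190
        assert res.delta == 578

    def test_unit_rr_no_change(self):
        res = model.project_counts(3612, 1.0, 5)
        assert res.projected == 3612 and res.delta == 0

    def test_two_degree_extension(self):
        assert model.project_counts(3612, 1.16, 2).projected == round(
            3612 * 1.16 ** 2
        )

    def test_cooling_scenario_allowed(self):
        res = model.project_counts(1000, 1.2, -1)
        assert res.projected == pytest.approx(1000 / 1.2, abs=1)
        assert res.delta < 0

    def test_invalid_rr_rejected(self):
        with pytest.raises(InvalidInputError):
            model.project_counts(100, 0.0, 1)
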