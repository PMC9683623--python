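"""Shared fixtures: small synthetic worlds built once per session."""

import numpy as np
import pytest

from heatrisk import annual, met, model, simulate


@pytest.fixture(scope="session")
def sites3():
    return simulate.default_sites(3)


@pytest.fixture(scope="session")
def derived_small(sites3):
    """Three sites, 8 years of hourly weather run through the physics."""
    met_df = simulate.gen_hourly_met(sites3, range(1990, 1998), seed=11)
    coords = {
        s.location_id: met.SiteCoords(s.latitude, s.longitude, s.utc_offset)
        for s in sites3
    }
    return met.derive_hourly(met_df, sites=coords)


@pytest.fixture(scope="session")
def daily_small(derived_small):
    return annual.daily_summaries(derived_small)


@pytest.fixture(scope="session")
def clim_small(daily_small):
    return annual.build_climatology(daily_small, baseline_years=(1990, 1997))


@pytest.fixture(scope="session")
def annual_small(derived_small, clim_small):
    return annual.compute_all_indices(derived_small, clim=clim_small)


@pytest.fixture(scope="session")
def sites10():
    return simulate.default_sites()


@pytest.fixture(scope="session")
def truth10(sites10):
    return simulate.default_truth(sites10)


@pytest.fixture(scope="session")
def panel_world(sites10, truth10):
    """Annual-scale exposure + NB2 outcome panel with known truth."""
    years = range(1991, 2019)
    expo = simulate.gen_annual_exposure(sites10, years, seed=21)
    pops = {s.location_id: s.population for s in sites10}
    pan = simulate.gen_outcome_panel(expo, truth10, pops, seed=22)
    return expo, pan


@pytest.fixture(scope="session")
def fitted_world(panel_world):
    expo, pan = panel_world
    spec = model.ModelSpec(reference_location="site_01", n_boot=200, seed=5)
    design = model.build_design(pan, expo, spec)
    return design, model.fit_negbin(design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
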