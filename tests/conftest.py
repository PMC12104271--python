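"""Shared fixtures: a reusable synthetic site network with weather."""

from __future__ import annotations

import numpy as np
import pytest

import phenohydro as ph


@pytest.fixture(scope="session")
def sites():
    return ph.default_sites(6)


@pytest.fixture(scope="session")
def weather_by_site(sites):
    """Six sites, 27 years of daily weather (seeded, generated once)."""
    return {s.site_id: ph.generate_weather(
        s, range(1999, 2026), ph.climate_for_site(s, seed=3))
        for s in sites}


@pytest.fixture(scope="session")
def small_weather(sites):
    """A lighter 7-year panel for pipeline-level tests."""
    return {s.site_id: ph.generate_weather(
        s, range(2001, 2008), ph.climate_for_site(s, seed=11))
        for s in sites[:4]}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
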