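"""Shared fixtures.

The confined-brush production runs are expensive, so they are produced
once per session by a caching factory and shared between the integration
and acceptance tests.  Seeds are fixed so every statistical assertion is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fbdsim import presets

settings.register_profile(
    "derandomized", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("derandomized")

#: replicate seeds for the scaled-brush production runs
BRUSH_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def brush_cache():
    """Caching factory for scaled bottle-brush production runs."""
    cache = {}

    def get(bond_type, hurst, seed, n_equil=20_000, n_production=100_000,
            track="mid-backbone"):
        key = (bond_type, hurst, seed, n_equil, n_production, str(track))
        if key not in cache:
            cache[key] = presets.run_scaled_brush(
                bond_type, hurst, seed, n_equil=n_equil,
                n_production=n_production, track=track)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def harmonic_runs_h05(brush_cache):
    """Three replicate harmonic-bond runs at H = 0.5 (standard BD)."""
    return [brush_cache("harmonic", 0.5, s) for s in BRUSH_SEEDS]


@pytest.fixture(scope="session")
def harmonic_runs_h045(brush_cache):
    """Three replicate harmonic-bond runs in the subdiffusive regime."""
    return [brush_cache("harmonic", 0.45, s) for s in BRUSH_SEEDS]


@pytest.fixture(scope="session")
def fene_run_h045(brush_cache):
    return brush_cache("fene", 0.45, BRUSH_SEEDS[0])


@pytest.fixture(scope="session")
def phenomenology_runs(brush_cache):
    """Shorter matched runs for energy/density comparisons across
    bond types and Hurst parameters."""
    out = {}
    for bond in ("fene", "harmonic"):
        for hurst in (0.5, 0.65):
            out[(bond, hurst)] = brush_cache(
                bond, hurst, 21, n_equil=5_000, n_production=40_000,
                track=None)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
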