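"""Shared fixtures: expensive simulated data built once per session."""

import numpy as np
import pytest

import critbif as cb
from critbif.avalanches import default_duration_range, induced_size_range

BROWNIAN_D = 5e-5
BROWNIAN_DT = 1e-3
BROWNIAN_DURATION = 1000.0  # 1e6 steps per run
BROWNIAN_N_RUNS = 10


@pytest.fixture(scope="session")
def brownian_catalog():
    """Pooled avalanche catalog from 10 seeded driftless runs (linear form
    at mu = 0): the Brownian reference for the exponent and crackling
    tests, with its default duration/size fitting ranges."""
    form = cb.normal_form("linear", 0.0)
    cfg = cb.SimConfig(duration=BROWNIAN_DURATION, dt=BROWNIAN_DT,
                       D=BROWNIAN_D, seed=100)
    seeds = [100 + i for i in range(BROWNIAN_N_RUNS)]
    trajs = cb.simulate_many(form, cfg, None, seeds)
    catalog = cb.pool_catalogs([cb.detect_avalanches(tr, 0.0) for tr in trajs])
    t_range = default_duration_range(BROWNIAN_DT, BROWNIAN_DURATION)
    s_range = induced_size_range(BROWNIAN_D, t_range)
    return catalog, t_range, s_range


@pytest.fixture(scope="session")
def brownian_fits(brownian_catalog):
    catalog, t_range, s_range = brownian_catalog
    fit_t = cb.fit_powerlaw_dist(catalog.durations, *t_range)
    fit_s = cb.fit_powerlaw_dist(catalog.sizes, *s_range)
    return fit_s, fit_t


def pitchfork_relaxation(mu, delta_factor=5.0, n_repeats=200, duration=8.0,
                         seed=1, settle=100.0, D=5e-5):
    """Pulse–relaxation curve of the supercritical pitchfork (the strong-
    stimulus probe protocol)."""
    constraint = "within_basin" if mu > 0 else "none"
    form = cb.normal_form("pitchfork_super", mu=mu, constraint=constraint)
    scales = cb.crossover_scales(form, D)
    delta = delta_factor * scales.xi_noise
    cfg = cb.SimConfig(duration=duration, dt=1e-3, D=D, settle_time=settle,
                       seed=seed, record_stride=10)
    trajs = cb.relaxation_ensemble(form, delta, n_repeats, cfg)
    return cb.relaxation_curve(
        trajs, 0.0, cb.tracked_fixed_point(form),
        condition={"xi_lin": scales.xi_lin, "xi_noise": scales.xi_noise,
                   "delta": delta})


@pytest.fixture(scope="session")
def pitchfork_curve_at_bifurcation():
    return pitchfork_relaxation(0.0, duration=120.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
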