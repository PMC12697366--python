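"""Entropy and mutual-information estimation from pulse-response ensembles."""

import math

import numpy as np
import pandas as pd
import pytest

import critbif as cb
from critbif.information import MITrialTable, DEFAULT_DELTAS


def _table(delta, x_tau, lag=1.0, meta=None):
    n = len(delta)
    df = pd.DataFrame({"trial": np.arange(n), "delta": delta,
                       "lag": lag, "x_tau": x_tau})
    return MITrialTable(data=df, meta=meta or {})


class TestEntropy:
    def test_uniform_over_four_bins_is_two_bits(self):
        samples = np.repeat([0.1, 0.3, 0.5, 0.7], 25)
        assert cb.entropy(samples, np.linspace(0, 0.8, 5)) == pytest.approx(2.0)

    def test_degenerate_cases(self):
        assert cb.entropy([0.5, 0.50001], 16) >= 0.0
        with pytest.warns(UserWarning):
            assert cb.entropy([1.0, 2.0, 3.0], 1) == 0.0
        assert cb.entropy(np.full(100, 2.0), np.linspace(0, 4, 9)) == 0.0
        with pytest.raises(ValueError):
            cb.entropy([1.0], 4)

    def test_matches_brute_force_histogram_entropy(self):
        """Plug-in entropy equals an independently coded histogram sum."""
        g = np.random.default_rng(3)
        samples = g.standard_normal(10_000)
        edges = np.linspace(-4, 4, 65)
        # brute force: count bin occupancy by hand
        idx = np.searchsorted(edges, samples, side="right") - 1
        idx = idx[(idx >= 0) & (idx < 64)]
        counts = np.bincount(idx, minlength=64)
        h = 0.0
        for c in counts:
            if c:
                p = c / counts.sum()
                h -= p * math.log2(p)
        assert cb.entropy(samples, edges) == pytest.approx(h, abs=1e-12)


class TestMutualInformation:
    def test_independent_channel_has_near_zero_information(self):
        g = np.random.default_rng(1)
        delta = np.tile(DEFAULT_DELTAS, 1000)
        res = cb.mutual_information(_table(delta, g.standard_normal(6000)))
        assert res.table["mi_bits"].iloc[0] == pytest.approx(0.0, abs=0.05)

    def test_noiseless_channel_saturates_at_log2_k(self):
        delta = np.tile(DEFAULT_DELTAS, 50)
        res = cb.mutual_information(_table(delta, np.asarray(delta)))
        assert res.table["mi_bits"].iloc[0] == pytest.approx(math.log2(6))
        assert res.table["hcond_bits"].iloc[0] == pytest.approx(0.0)

    def test_identity_and_bounds(self):
        """I = H - H_cond by construction and 0 <= I <= log2(#deltas)."""
        g = np.random.default_rng(2)
        delta = np.tile(DEFAULT_DELTAS, 100)
        x = np.asarray(delta) + 0.3 * g.standard_normal(600)
        res = cb.mutual_information(_table(delta, x))
        row = res.table.iloc[0]
        assert row["mi_bits"] == pytest.approx(
            row["h_bits"] - row["hcond_bits"], abs=1e-12)
        assert -1e-9 <= row["mi_bits"] <= math.log2(6) + 1e-9

    def test_coarser_bins_never_gain_information(self):
        """Data-processing inequality on nested discretizations."""
        g = np.random.default_rng(4)
        delta = np.tile(DEFAULT_DELTAS, 200)
        x = np.asarray(delta) + 0.2 * g.standard_normal(1200)
        mis = [cb.mutual_information(_table(delta, x), n_bins=nb,
                                     bin_range=(-1.0, 2.0)).table["mi_bits"].iloc[0]
               for nb in (64, 32, 16)]
        assert mis[0] >= mis[1] >= mis[2]

    def test_small_cells_excluded_with_warning(self):
        delta = np.array([0.1] * 40 + [0.2] * 40 + [0.3] * 5)
        with pytest.warns(UserWarning):
            res = cb.mutual_information(_table(delta, delta * 1.0))
        assert res.table["mi_bits"].iloc[0] == pytest.approx(1.0)  # 2 cells left


class TestTrials:
    def test_round_robin_allocation(self):
        form = cb.normal_form("linear", -1.0)
        cfg = cb.SimConfig(duration=2.0, dt=1e-3, D=1e-4, settle_time=0.5,
                           seed=11, record_stride=10)
        tab = cb.run_mi_trials(form, cfg, lags=[1.0, 2.0], n_trials=6)
        counts = tab.data.groupby("delta")["trial"].nunique()
        assert set(counts.index) == set(DEFAULT_DELTAS)
        assert (counts == 1).all()

    def test_deterministic_dynamics_give_identical_readouts(self):
        form = cb.normal_form("pitchfork_super", -1.0)
        cfg = cb.SimConfig(duration=2.0, dt=1e-3, D=0.0, seed=0,
                           record_stride=10)
        tab = cb.run_mi_trials(form, cfg, delta_set=[0.2, 0.5],
                               lags=[1.0], n_trials=10)
        spread = tab.data.groupby("delta")["x_tau"].std()
        assert np.allclose(spread, 0.0)

    def test_brownian_readout_variance_grows_with_lag(self):
        """Linear form at mu=0: Var[x_tau] across trials ~ 2 D (settle+lag)."""
        D = 1e-3
        form = cb.normal_form("linear", 0.0)
        cfg = cb.SimConfig(duration=8.0, dt=1e-3, D=D, settle_time=0.0,
                           seed=21, record_stride=10)
        tab = cb.run_mi_trials(form, cfg, delta_set=[0.0], lags=[2.0, 8.0],
                               n_trials=2000)
        v = tab.data.groupby("lag")["x_tau"].var()
        assert v[8.0] / v[2.0] == pytest.approx(4.0, rel=0.15)


def test_information_peaks_at_the_bifurcation():
    """MI at a fixed lag is maximal at mu = 0 (pitchfork sweep)."""
    cfg = cb.SimConfig(duration=5.0, dt=1e-3, D=5e-5, settle_time=30.0,
                       seed=31, record_stride=10)
    df = cb.mi_sweep("pitchfork_super", [-1.0, 0.0], cfg, lags=[5.0],
                     n_trials=200)
    mi = df.set_index("mu")["mi_bits"]
    assert mi[0.0] > mi[-1.0]


def test_transcritical_symmetric_pitchfork_asymmetric():
    """Equidistant sweeps above/below the bifurcation give matching MI for
    the transcritical form (mirror-symmetric local dynamics) but not for
    the pitchfork (the linearized rate doubles above)."""
    lag, amu = 3.0, 0.5
    cfg = cb.SimConfig(duration=lag, dt=1e-3, D=5e-5, settle_time=30.0,
                       seed=41, record_stride=10)

    def gap(form_name):
        df = cb.mi_sweep(form_name, [-amu, amu], cfg, lags=[lag],
                         n_trials=400)
        mi = df.set_index("mu")["mi_bits"]
        return abs(mi[amu] - mi[-amu])

    # Monte-Carlo scale of the MI estimate: spread over independent blocks
    form = cb.normal_form("pitchfork_super", -amu, constraint="within_basin")
    reps = []
    for k in range(4):
        c = cb.SimConfig(duration=lag, dt=1e-3, D=5e-5, settle_time=30.0,
                         seed=2000 + 500 * k, record_stride=10)
        tab = cb.run_mi_trials(form, c, lags=[lag], n_trials=400)
        reps.append(cb.mutual_information(tab).table["mi_bits"].iloc[0])
    mc_error = 3 * np.std(reps, ddof=1)
    assert gap("transcritical") < max(mc_error, 0.1)
    assert gap("pitchfork_super") > max(mc_error, 0.1)


def test_brownian_system_retains_information_longest():
    """At the bifurcation the linear (Brownian) system keeps stimulus
    information across delays while the nonlinear forms lose it, at the
    price of much larger conditional entropy (unreliable responses);
    entropies compared on one shared absolute binning."""
    cfg = cb.SimConfig(duration=15.0, dt=1e-3, D=5e-5, settle_time=60.0,
                       seed=21, record_stride=10)
    res = {}
    for name, constraint in (("linear", "none"),
                             ("pitchfork_super", "within_basin"),
                             ("transcritical", "positive_only")):
        form = cb.normal_form(name, 0.0, constraint=constraint)
        tab = cb.run_mi_trials(form, cfg, lags=[5.0, 15.0], n_trials=300)
        res[name] = cb.mutual_information(
            tab, n_bins=64, bin_range=(-1.0, 2.0)).table.set_index("lag")

    def decay(name):
        return res[name]["mi_bits"][5.0] - res[name]["mi_bits"][15.0]

    assert decay("linear") < decay("pitchfork_super")
    assert decay("linear") < decay("transcritical")
    for name in ("pitchfork_super", "transcritical"):
        assert (res["linear"]["hcond_bits"][15.0]
                > res[name]["hcond_bits"][15.0])
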