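"""Normal-form definitions: drift, fixed points, exponents, crossovers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import critbif as cb
from critbif.forms import FORM_NAMES, drift_derivative

pytestmark = []


@pytest.mark.parametrize(
    "name,mu,x,expected",
    [
        ("pitchfork_super", 0.0, 0.0, 0.0),
        ("pitchfork_super", 1.0, 1.0, 0.0),   # x* = sqrt(mu)
        ("transcritical", 0.0, 0.5, -0.25),
        ("linear", -2.0, 3.0, -6.0),
        ("saddle_node", 1.0, 0.0, 1.0),
        ("pitchfork_sub", 0.0, 2.0, 8.0),
        ("hopf_super", 1.0, 2.0, -6.0),
    ],
)
def test_drift_values(name, mu, x, expected):
    assert cb.drift(cb.normal_form(name, mu), x) == pytest.approx(expected)


def test_unknown_form_rejected():
    with pytest.raises(ValueError):
        cb.normal_form("homoclinic")


@pytest.mark.parametrize(
    "name,mu,expected",
    [
        ("pitchfork_super", -1.0, [(0.0, "stable")]),
        ("pitchfork_super", 1.0,
         [(-1.0, "stable"), (0.0, "unstable"), (1.0, "stable")]),
        ("transcritical", 0.0, [(0.0, "marginal")]),
        ("saddle_node", -1.0, []),
        ("saddle_node", 4.0, [(-2.0, "unstable"), (2.0, "stable")]),
        ("hopf_super", 1.0, [(0.0, "unstable"), (1.0, "stable")]),  # r >= 0
    ],
)
def test_fixed_points(name, mu, expected):
    pts = cb.fixed_points(cb.normal_form(name, mu))
    assert len(pts) == len(expected)
    for (x, s), (xe, se) in zip(pts, expected):
        assert x == pytest.approx(xe, abs=1e-9)
        assert s == se


@settings(max_examples=150, derandomize=True)
@given(
    name=st.sampled_from(FORM_NAMES),
    mu=st.floats(-3.0, 3.0, allow_nan=False),
)
def test_fixed_points_are_roots_with_consistent_stability(name, mu):
    """Every reported fixed point is a root of the drift, and its label
    agrees with a central-difference derivative of the drift."""
    form = cb.normal_form(name, mu)
    h = 1e-6
    for x, stab in cb.fixed_points(form):
        assert abs(cb.drift(form, x)) < 1e-12
        num = (cb.drift(form, x + h) - cb.drift(form, x - h)) / (2 * h)
        if stab == "stable":
            assert num < 1e-4
        elif stab == "unstable":
            assert num > -1e-4
        else:
            assert abs(num) < 1e-4


def test_relaxation_exponent_table():
    """alpha = 1/(n-1) for restoring forms; none for linear/subcritical."""
    expected = {
        "linear": None,
        "saddle_node": 1.0,
        "transcritical": 1.0,
        "pitchfork_super": 0.5,
        "pitchfork_sub": None,
        "hopf_super": 0.5,
        "hopf_sub": None,
    }
    for name, alpha in expected.items():
        form = cb.normal_form(name)
        got = cb.relaxation_exponent(form)
        assert got == alpha
        if got is not None:
            assert got == pytest.approx(1.0 / (form.n - 1))


class TestCrossoverScales:
    def test_xi_lin_vanishes_at_bifurcation(self):
        s = cb.crossover_scales(cb.normal_form("pitchfork_super", 0.0), D=1e-4)
        assert s.xi_lin == 0.0

    def test_unit_ratio(self):
        # D = |c| makes the ratio 1 regardless of the exponent
        for name in ("pitchfork_super", "transcritical", "pitchfork_sub"):
            s = cb.crossover_scales(cb.normal_form(name, 0.3), D=1.0)
            assert s.xi_noise == pytest.approx(1.0)

    def test_quartic_root_value(self):
        s = cb.crossover_scales(cb.normal_form("pitchfork_super", 0.0), D=5e-5)
        assert s.xi_noise == pytest.approx(5e-5 ** 0.25, rel=1e-12)
        assert s.xi_noise == pytest.approx(0.0841, abs=5e-5)

    def test_monotone_in_D_and_mu(self):
        form = cb.normal_form("pitchfork_super", 0.0)
        xs = [cb.crossover_scales(form, D).xi_noise
              for D in (1e-6, 1e-5, 1e-4, 1e-3)]
        assert all(a < b for a, b in zip(xs, xs[1:]))
        xl = [cb.crossover_scales(form.with_mu(mu), 0.0).xi_lin
              for mu in (0.0, 0.01, 0.1, 1.0)]
        assert xl[0] == 0.0 and all(a < b for a, b in zip(xl, xl[1:]))

    def test_linear_form_markers(self):
        s = cb.crossover_scales(cb.normal_form("linear", -1.0), D=1e-4)
        assert math.isinf(s.xi_lin) and math.isnan(s.xi_noise)

    def test_negative_D_rejected(self):
        with pytest.raises(ValueError):
            cb.crossover_scales(cb.normal_form("pitchfork_super"), D=-1.0)


class TestClassification:
    def test_anchor_verdicts(self):
        assert cb.classify_criticality(
            cb.normal_form("pitchfork_super")).biologically_plausible
        assert cb.classify_criticality(
            cb.normal_form("hopf_super")).biologically_plausible
        assert cb.classify_criticality(
            cb.normal_form("transcritical", constraint="positive_only")
        ).biologically_plausible
        for name in ("saddle_node", "pitchfork_sub", "hopf_sub", "linear",
                     "transcritical"):
            assert not cb.classify_criticality(
                cb.normal_form(name)).biologically_plausible

    def test_linear_is_brownian_critical_only(self):
        v = cb.classify_criticality(cb.normal_form("linear"))
        assert v.deterministic_scale_invariance == "no"
        assert v.brownian_scale_invariance

    def test_plausibility_invariant(self):
        """Plausible requires scale invariance plus both robustness flags."""
        for name in FORM_NAMES:
            for constraint in ("none", "positive_only"):
                v = cb.classify_criticality(
                    cb.normal_form(name, constraint=constraint))
                if v.biologically_plausible:
                    assert (v.deterministic_scale_invariance != "no"
                            or v.brownian_scale_invariance)
                    assert v.robust_to_order_noise
                    assert v.robust_to_control_noise

    def test_exponent_matches_sidedness(self):
        """Symmetric power-law forms are odd-n, one-sided forms even-n."""
        for name in FORM_NAMES:
            form = cb.normal_form(name)
            v = cb.classify_criticality(form)
            if v.deterministic_scale_invariance == "yes_symmetric":
                assert form.n % 2 == 1
            elif v.deterministic_scale_invariance == "yes_one_sided":
                assert form.n % 2 == 0
            else:
                assert cb.relaxation_exponent(form) is None
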