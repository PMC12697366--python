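"""Canonical bifurcation normal forms and their criticality taxonomy.

Each form is a one-dimensional drift ``f(x, mu)`` whose nonlinear part is
written as ``-c * x**n`` so that ``c > 0`` is restoring (supercritical) and
``c < 0`` anti-restoring (subcritical).  The Hopf forms are represented by
their radial amplitude equation only: the oscillation amplitude is the order
parameter and carries all the scale-invariance content, so the angular
variable is dropped.  The bifurcation sits at ``mu = 0`` for every form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "FORM_NAMES",
    "NormalForm",
    "CrossoverScales",
    "CriticalityVerdict",
    "normal_form",
    "drift",
    "drift_derivative",
    "fixed_points",
    "relaxation_exponent",
    "crossover_scales",
    "classify_criticality",
]

FORM_NAMES = (
    "linear",
    "saddle_node",
    "transcritical",
    "pitchfork_super",
    "pitchfork_sub",
    "hopf_super",
    "hopf_sub",
)

# (n, c, radial, observable) per form; drift = a0 + a1*x - c*x**n with
# a0 = mu for the saddle node (constant term) and a1 = mu otherwise.
_CANON = {
    "linear": (0, 0.0, False, "identity"),
    "saddle_node": (2, 1.0, False, "identity"),
    "transcritical": (2, 1.0, False, "identity"),
    "pitchfork_super": (3, 1.0, False, "identity"),
    "pitchfork_sub": (3, -1.0, False, "identity"),
    "hopf_super": (3, 1.0, True, "radial amplitude"),
    "hopf_sub": (3, -1.0, True, "radial amplitude"),
}

CONSTRAINTS = ("none", "positive_only", "within_basin")


@dataclass(frozen=True)
class NormalForm:
    """A named bifurcation normal form at a fixed control-parameter value.

    Parameters
    ----------
    name : str
        One of :data:`FORM_NAMES`.
    mu : float
        Control parameter (dimensionless); the bifurcation is at ``mu = 0``.
    n : int
        Order of the leading nonlinear term (0 for the purely linear form).
    c : float
        Coefficient of the leading nonlinearity, drift nonlinear part
        ``-c * x**n``; ``c > 0`` restoring.
    constraint : str
        State constraint enforced by the integrator: ``none``,
        ``positive_only`` (reflecting wall at 0) or ``within_basin``
        (reflect at the basin border of the tracked stable fixed point).
    observable : str
        Description of the order-parameter map.
    """

    name: str
    mu: float = 0.0
    n: int = field(default=0)
    c: float = field(default=0.0)
    constraint: str = "none"
    observable: str = "identity"

    def __post_init__(self):
        if self.name not in _CANON:
            raise ValueError(
                f"unknown normal form {self.name!r}; choose from {FORM_NAMES}"
            )
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"unknown constraint {self.constraint!r}")

    @property
    def radial(self) -> bool:
        return _CANON[self.name][2]

    def with_mu(self, mu: float) -> "NormalForm":
        return replace(self, mu=float(mu))


def normal_form(name: str, mu: float = 0.0, constraint: str = "none") -> NormalForm:
    """Build a :class:`NormalForm` with its canonical ``n``, ``c`` and observable."""
    if name not in _CANON:
        raise ValueError(f"unknown normal form {name!r}; choose from {FORM_NAMES}")
    n, c, _radial, obs = _CANON[name]
    return NormalForm(name=name, mu=float(mu), n=n, c=c,
                      constraint=constraint, observable=obs)


def drift_coefficients(form: NormalForm) -> tuple[float, float, float, int]:
    """Return ``(a0, a1, c, n)`` with drift ``a0 + a1*x - c*x**n``."""
    if form.name == "saddle_node":
        return form.mu, 0.0, form.c, form.n
    if form.name == "linear":
        return 0.0, form.mu, 0.0, 0
    return 0.0, form.mu, form.c, form.n


def drift(form: NormalForm, x):
    """Deterministic drift f(x, mu) of the form, vectorized over ``x``.

    linear -> mu*x; saddle_node -> mu - x^2; transcritical -> mu*x - x^2;
    pitchfork/Hopf (radial) -> mu*x -+ x^3.
    """
    a0, a1, c, n = drift_coefficients(form)
    x = np.asarray(x, dtype=float)
    out = a0 + a1 * x
    if c != 0.0:
        out = out - c * x**n
    return out if out.ndim else float(out)


def drift_derivative(form: NormalForm, x):
    """Analytic df/dx, used for linear stability."""
    a0, a1, c, n = drift_coefficients(form)
    x = np.asarray(x, dtype=float)
    out = a1 * np.ones_like(x)
    if c != 0.0:
        out = out - n * c * x ** (n - 1)
    return out if out.ndim else float(out)


_STAB_TOL = 1e-9


def fixed_points(form: NormalForm) -> list[tuple[float, str]]:
    """All real fixed points of the drift with their linear stability.

    Returns a list of ``(x_star, stability)`` with stability in
    ``{"stable", "unstable", "marginal"}`` (marginal when the linearization
    vanishes).  The saddle node below the bifurcation (mu < 0) has no real
    fixed points and returns an empty list.  Hopf (radial) forms report only
    amplitudes r >= 0.
    """
    a0, a1, c, n = drift_coefficients(form)
    # polynomial coefficients, highest power first
    if c == 0.0:
        coeffs = [a1, a0]
        if a1 == 0.0:  # drift identically a0
            return [] if a0 != 0.0 else [(0.0, "marginal")]
    else:
        coeffs = [0.0] * (n + 1)
        coeffs[0] = -c
        coeffs[-1] = a0
        coeffs[-2] = a1
    roots = np.roots(coeffs)
    out = []
    seen: list[float] = []
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        xr = float(r.real)
        if abs(xr) < 1e-12:
            xr = 0.0
        if any(abs(xr - s) < 1e-9 for s in seen):
            continue
        if form.radial and xr < -1e-12:
            continue
        seen.append(xr)
        fp = drift_derivative(form, xr)
        if abs(fp) < _STAB_TOL:
            stab = "marginal"
        elif fp < 0:
            stab = "stable"
        else:
            stab = "unstable"
        out.append((xr, stab))
    out.sort(key=lambda p: p[0])
    return out


def tracked_fixed_point(form: NormalForm) -> float:
    """The stable (or marginal) fixed point the experiments track.

    Convention: the continuation of the quiescent branch — 0 for mu <= 0;
    above the bifurcation, sqrt(mu) for pitchfork/Hopf supercritical, mu for
    the transcritical, sqrt(mu) for the saddle node; 0 for the linear form.
    """
    mu = form.mu
    if form.name == "linear" or mu <= 0:
        if form.name == "saddle_node":
            return math.sqrt(mu) if mu > 0 else 0.0
        return 0.0
    if form.name in ("pitchfork_super", "hopf_super"):
        return math.sqrt(mu)
    if form.name == "transcritical":
        return mu
    if form.name == "saddle_node":
        return math.sqrt(mu)
    return 0.0  # subcritical forms: origin while it lasts


@dataclass(frozen=True)
class CrossoverScales:
    """Crossover scales of a form, in order-parameter units.

    ``xi_lin``: scale where linear and nonlinear drift balance — relaxation is
    power law above it and exponential below it; vanishes at the bifurcation.
    ``xi_noise``: scale where nonlinear drift balances diffusion — Brownian
    below, drift-dominated above.  Proportionality constants are fixed to 1.
    """

    xi_lin: float
    xi_noise: float


def crossover_scales(form: NormalForm, D: float = 0.0) -> CrossoverScales:
    """Compute (xi_lin, xi_noise) = ((|mu|/|c|)^{1/(n-1)}, (D/|c|)^{1/(n+1)}).

    The linear form has no nonlinearity: xi_lin is infinite (the exponential
    regime extends to any amplitude) and xi_noise is undefined (NaN).
    """
    if D < 0:
        raise ValueError("diffusion constant D must be non-negative")
    if form.c == 0.0:
        return CrossoverScales(xi_lin=math.inf, xi_noise=math.nan)
    ac = abs(form.c)
    xi_lin = (abs(form.mu) / ac) ** (1.0 / (form.n - 1))
    xi_noise = (D / ac) ** (1.0 / (form.n + 1))
    return CrossoverScales(xi_lin=xi_lin, xi_noise=xi_noise)


def relaxation_exponent(form: NormalForm) -> Optional[float]:
    """Power-law exponent alpha of the critical relaxation delta_x ~ t^-alpha.

    alpha = 1/(n-1) when the leading nonlinearity is restoring along the
    approach direction (symmetric for odd n, one-sided for even n); ``None``
    for the linear form (exponential at any amplitude) and for subcritical
    forms (anti-restoring nonlinearity, perturbations fly away).
    """
    if form.c > 0 and form.n >= 2:
        return 1.0 / (form.n - 1)
    return None


@dataclass(frozen=True)
class CriticalityVerdict:
    """One row of the criticality/plausibility taxonomy.

    A form is biologically plausible only if it is scale invariant by at
    least one route (deterministic power-law relaxation or Brownian
    fluctuations) and robust to noise in both the order parameter and the
    control parameter (no fly-away regime within reach).
    """

    deterministic_scale_invariance: str  # yes_symmetric | yes_one_sided | no
    brownian_scale_invariance: bool
    robust_to_order_noise: bool
    robust_to_control_noise: bool
    biologically_plausible: bool


_VERDICTS = {
    # name (constraint-sensitive for transcritical):
    "linear": CriticalityVerdict("no", True, False, False, False),
    "saddle_node": CriticalityVerdict("yes_one_sided", True, False, False, False),
    "transcritical": CriticalityVerdict("yes_one_sided", True, False, True, False),
    "transcritical+positive_only": CriticalityVerdict(
        "yes_one_sided", True, True, True, True
    ),
    "pitchfork_super": CriticalityVerdict("yes_symmetric", True, True, True, True),
    "pitchfork_sub": CriticalityVerdict("no", False, False, False, False),
    "hopf_super": CriticalityVerdict("yes_symmetric", True, True, True, True),
    "hopf_sub": CriticalityVerdict("no", False, False, False, False),
}


def classify_criticality(form: NormalForm) -> CriticalityVerdict:
    """Criticality and biological-plausibility verdict for a form.

    The transcritical form is plausible only when confined to x > 0
    (``constraint="positive_only"``); unbounded it can fly away through the
    negative axis.
    """
    key = form.name
    if form.name == "transcritical" and form.constraint == "positive_only":
        key = "transcritical+positive_only"
    return _VERDICTS[key]
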