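"""Perturbation–relaxation analysis: power-law vs exponential decay.

A relaxation curve is the ensemble mean of the signed displacement from the
tracked fixed point, aligned at the pulse.  At a critical bifurcation the
mean response of a form with restoring leading nonlinearity x^n decays as
t^{-1/(n-1)}; away from the bifurcation (or below the linear crossover
xi_lin) it decays exponentially with the linearized time constant, which
diverges as mu -> 0 (critical slowing down).  Fits are ordinary least
squares on the linearizing axes: log response vs log lag for the power law,
log response vs lag for the exponential — linearity on the respective axes
is the signature of each regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import Trajectory
from .forms import CrossoverScales

__all__ = [
    "RelaxationCurve",
    "DecayFit",
    "FitError",
    "relaxation_curve",
    "fit_power_law_decay",
    "fit_exponential_decay",
    "classify_regimes",
]

log = logging.getLogger(__name__)

_MIN_POINTS = 10


class FitError(ValueError):
    """Raised when a decay fit has too few usable points."""


@dataclass
class RelaxationCurve:
    """Mean relaxation after a pulse: lag grid, mean signed displacement
    (x - x*), per-lag standard error, and the generating condition."""

    lag: np.ndarray
    response: np.ndarray
    sem: np.ndarray
    condition: dict

    def __len__(self):
        return len(self.lag)


@dataclass
class DecayFit:
    """Result of one decay fit.

    Exactly one of ``alpha`` (power-law exponent) / ``tau_r`` (exponential
    relaxation time, seconds) is set, matching ``kind``; ``r_squared`` is the
    goodness of the straight-line fit on the transformed axes.
    """

    kind: str  # "power_law" | "exponential"
    alpha: Optional[float]
    tau_r: Optional[float]
    window: tuple[float, float]
    r_squared: float
    n_points: int = 0

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "alpha": self.alpha,
            "tau_r": self.tau_r,
            "window": list(self.window),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def relaxation_curve(
    trajectories: Sequence[Trajectory],
    pulse_time: float = 0.0,
    x_star: float = 0.0,
    condition: Optional[dict] = None,
) -> RelaxationCurve:
    """Average an ensemble of pulsed trajectories into a relaxation curve.

    Diverged trajectories are excluded (with a logged count); more than 50%
    diverged is an error.  All repeats must share the time grid.
    """
    good = [tr for tr in trajectories if not tr.diverged]
    n_excluded = len(trajectories) - len(good)
    if n_excluded:
        log.warning("relaxation_curve: excluded %d diverged trajectories",
                    n_excluded)
    if len(good) < max(1, math.ceil(len(trajectories) / 2)):
        raise ValueError(
            f"{n_excluded}/{len(trajectories)} trajectories diverged (>50%)"
        )
    t = good[0].t
    i0 = int(np.argmin(np.abs(t - pulse_time)))
    stack = np.stack([tr.x for tr in good])  # (n_rep, n_t)
    disp = stack[:, i0:] - x_star
    mean = disp.mean(axis=0)
    if len(good) > 1:
        sem = disp.std(axis=0, ddof=1) / math.sqrt(len(good))
    else:
        sem = np.zeros_like(mean)
    cond = dict(good[0].meta)
    cond["n_repeats"] = len(good)
    cond["n_excluded"] = n_excluded
    cond["x_star"] = x_star
    if condition:
        cond.update(condition)
    return RelaxationCurve(lag=t[i0:] - t[i0], response=mean, sem=sem,
                           condition=cond)


def _auto_shrink(lag, resp, window):
    """Restrict to the window; stop at the first non-positive response."""
    lo, hi = window
    m = (lag >= lo) & (lag <= hi) & (lag > 0)
    idx = np.where(m)[0]
    if len(idx) == 0:
        return idx
    nonpos = np.where(resp[idx] <= 0)[0]
    if len(nonpos):
        idx = idx[: nonpos[0]]
    return idx


def _auto_window_power(curve: RelaxationCurve) -> tuple[float, float]:
    """Default scaling window: from where the response has fallen to half
    its pulse amplitude (the power-law regime has set in) down to the
    crossover scale — xi_noise for noisy runs, xi_lin otherwise."""
    r0 = curve.response[0]
    xi = _crossing_scale(curve)
    lo = _first_below(curve, r0 / 2.0)
    hi = _first_below(curve, xi)
    return lo, hi


def _auto_window_exp(curve: RelaxationCurve) -> tuple[float, float]:
    """Default exponential window: start once the response is below
    min(delta_x, xi_lin / 3), where the linearization is accurate; end at
    the ensemble noise floor (3x the median SEM) — the ensemble *mean* stays
    exponential below xi_noise because the noise averages out."""
    r0 = curve.response[0]
    xi_lin = curve.condition.get("xi_lin", math.inf)
    start_level = min(r0, xi_lin / 3.0) if math.isfinite(xi_lin) else r0
    lo = _first_below(curve, start_level * (1 - 1e-12))
    floor = 3.0 * float(np.median(curve.sem))
    if floor <= 0:
        floor = max(abs(r0), 1.0) * 1e-10
    hi = _first_below(curve, floor)
    return lo, hi


def _crossing_scale(curve: RelaxationCurve) -> float:
    D = curve.condition.get("D", 0.0)
    if D and D > 0:
        return curve.condition.get("xi_noise", 0.0)
    return curve.condition.get("xi_lin", 0.0)


def _first_below(curve: RelaxationCurve, level: float) -> float:
    below = np.where(curve.response <= level)[0]
    if len(below) == 0 or not np.isfinite(level):
        return float(curve.lag[-1])
    i = below[0]
    return float(curve.lag[max(i, 1)])


def _linefit(u, v):
    slope, intercept = np.polyfit(u, v, 1)
    pred = slope * u + intercept
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def fit_power_law_decay(
    curve: RelaxationCurve, window: Optional[tuple[float, float]] = None
) -> DecayFit:
    """Least-squares slope of log(response) vs log(lag); alpha = -slope."""
    if window is None:
        window = _auto_window_power(curve)
    idx = _auto_shrink(curve.lag, curve.response, window)
    if len(idx) < _MIN_POINTS:
        raise FitError(
            f"power-law fit window {window} holds {len(idx)} points (<{_MIN_POINTS})"
        )
    u = np.log(curve.lag[idx])
    v = np.log(curve.response[idx])
    slope, r2 = _linefit(u, v)
    return DecayFit("power_law", alpha=-slope, tau_r=None,
                    window=(float(curve.lag[idx[0]]), float(curve.lag[idx[-1]])),
                    r_squared=r2, n_points=len(idx))


def fit_exponential_decay(
    curve: RelaxationCurve, window: Optional[tuple[float, float]] = None
) -> DecayFit:
    """Least-squares slope of log(response) vs lag; tau_r = -1/slope."""
    if window is None:
        window = _auto_window_exp(curve)
    idx = _auto_shrink(curve.lag, curve.response, window)
    if len(idx) < _MIN_POINTS:
        raise FitError(
            f"exponential fit window {window} holds {len(idx)} points (<{_MIN_POINTS})"
        )
    u = curve.lag[idx]
    v = np.log(curve.response[idx])
    slope, r2 = _linefit(u, v)
    tau = -1.0 / slope if slope < 0 else math.inf
    return DecayFit("exponential", alpha=None, tau_r=tau,
                    window=(float(u[0]), float(u[-1])),
                    r_squared=r2, n_points=len(idx))


def classify_regimes(
    curve: RelaxationCurve, scales: CrossoverScales
) -> list[tuple[tuple[float, float], str]]:
    """Split the curve at the relevant crossover and label each segment.

    Deterministic runs split where the response crosses xi_lin; noisy runs
    where it crosses xi_noise, and the sub-xi_noise segment is labeled
    ``noise_floor`` (Brownian fluctuations dominate there).  Each remaining
    segment is labeled by the better-fitting model (higher r^2 on the
    linearizing transform).
    """
    D = curve.condition.get("D", 0.0)
    noisy = bool(D and D > 0)
    xi = scales.xi_noise if noisy else scales.xi_lin
    segments: list[tuple[np.ndarray, Optional[str]]] = []
    if not np.isfinite(xi):
        segments.append((np.arange(1, len(curve.lag)), None))
    else:
        below = np.where(curve.response <= xi)[0]
        i_cross = int(below[0]) if len(below) else len(curve.lag)
        if i_cross > 1:
            segments.append((np.arange(1, i_cross), None))
        if i_cross < len(curve.lag):
            tail = np.arange(i_cross, len(curve.lag))
            segments.append((tail, "noise_floor" if noisy else None))
    out = []
    for idx, label in segments:
        if len(idx) == 0:
            continue
        span = (float(curve.lag[idx[0]]), float(curve.lag[idx[-1]]))
        if label is None:
            label = _better_model(curve, span)
        out.append((span, label))
    return out


def _better_model(curve: RelaxationCurve, span: tuple[float, float]) -> str:
    try:
        pl = fit_power_law_decay(curve, window=span)
    except FitError:
        pl = None
    try:
        ex = fit_exponential_decay(curve, window=span)
    except FitError:
        ex = None
    if pl is None and ex is None:
        return "noise_floor"
    if pl is None:
        return "exponential"
    if ex is None:
        return "power_law"
    return "power_law" if pl.r_squared >= ex.r_squared else "exponential"
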