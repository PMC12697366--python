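"""Threshold-excursion avalanches and crackling-noise scaling.

An avalanche is a contiguous excursion of the order parameter above a
threshold; its duration T is the excursion length and its size S the
integrated excess area, S = dt * sum(x - threshold).  For driftless
(Brownian) dynamics at a bifurcation the excursions are scale invariant
with duration exponent tau_T = 3/2 (first-passage law) and size exponent
tau_S = 4/3, and the mean size conditioned on duration obeys the
crackling-noise relation <S>(T) ~ T^gamma with gamma = (tau_T-1)/(tau_S-1).

Exponents are fitted by continuous maximum likelihood for a power law
truncated to a bounded range [x_min, x_max], with a Kolmogorov–Smirnov
distance as the goodness statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .engine import Trajectory

__all__ = [
    "AvalancheCatalog",
    "PowerLawFit",
    "PowerLawFitError",
    "detect_avalanches",
    "pool_catalogs",
    "fit_powerlaw_dist",
    "sample_truncated_powerlaw",
    "crackling_check",
    "CracklingResult",
    "default_duration_range",
    "induced_size_range",
]

_MIN_TAIL = 50


class PowerLawFitError(ValueError):
    def __init__(self, msg: str, n_tail: int):
        super().__init__(msg)
        self.n_tail = n_tail


@dataclass
class AvalancheCatalog:
    """Excursion events of one (or several pooled) time series."""

    sizes: np.ndarray  # order-parameter * seconds, strictly positive
    durations: np.ndarray  # seconds, >= sampling interval
    start_indices: np.ndarray
    threshold: float
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.sizes)


def detect_avalanches(traj: Trajectory, threshold: float = 0.0) -> AvalancheCatalog:
    """Extract excursions of ``traj.x`` strictly above ``threshold``.

    Runs touching either end of the series are discarded (their true extent
    is censored).  An all-below series yields an empty catalog with a
    warning, not an error.
    """
    x = np.asarray(traj.x, dtype=float)
    dt = traj.dt_sample
    above = x > threshold
    if not above.any():
        warnings.warn("threshold above all samples: empty avalanche catalog")
        empty = np.empty(0)
        return AvalancheCatalog(empty, empty.copy(),
                                np.empty(0, dtype=int), threshold,
                                meta=dict(traj.meta))
    edges = np.diff(above.astype(np.int8))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1  # first index back at/below threshold
    if above[0] and len(ends):  # run censored at the left edge
        ends = ends[1:]
    n = min(len(starts), len(ends))  # trailing run censored at the right edge
    starts, ends = starts[:n], ends[:n]
    durations = (ends - starts) * dt
    cum = np.concatenate([[0.0], np.cumsum(x - threshold)])
    sizes = (cum[ends] - cum[starts]) * dt
    keep = sizes > 0
    return AvalancheCatalog(
        sizes=sizes[keep],
        durations=durations[keep],
        start_indices=starts[keep],
        threshold=float(threshold),
        meta=dict(traj.meta),
    )


def pool_catalogs(catalogs: Sequence[AvalancheCatalog]) -> AvalancheCatalog:
    """Pool events from independent runs of one condition.

    Pooling catalogs (rather than concatenating raw series) avoids the
    artificial threshold crossings a concatenation seam would create.
    """
    if not catalogs:
        raise ValueError("no catalogs to pool")
    thr = catalogs[0].threshold
    if any(abs(c.threshold - thr) > 1e-12 for c in catalogs):
        raise ValueError("catalogs have differing thresholds")
    return AvalancheCatalog(
        sizes=np.concatenate([c.sizes for c in catalogs]),
        durations=np.concatenate([c.durations for c in catalogs]),
        start_indices=np.concatenate([c.start_indices for c in catalogs]),
        threshold=thr,
        meta={"pooled_runs": len(catalogs), **dict(catalogs[0].meta)},
    )


@dataclass
class PowerLawFit:
    """MLE of a truncated continuous power law p(x) ~ x^-exponent on
    [x_min, x_max], with the KS distance on that range."""

    exponent: float
    x_min: float
    x_max: float
    n_tail: int
    ks_distance: float


def _trunc_cdf(x, tau, lo, hi):
    if abs(tau - 1.0) < 1e-12:
        return (np.log(x) - math.log(lo)) / (math.log(hi) - math.log(lo))
    e = 1.0 - tau
    return (x**e - lo**e) / (hi**e - lo**e)


def fit_powerlaw_dist(
    samples: Sequence[float], x_min: float, x_max: float
) -> PowerLawFit:
    """Continuous MLE of the exponent of a power law truncated to
    [x_min, x_max]; requires >= 50 samples in range."""
    if not (0 < x_min < x_max):
        raise ValueError("need 0 < x_min < x_max")
    s = np.asarray(samples, dtype=float)
    s = s[(s >= x_min) & (s <= x_max)]
    n = len(s)
    if n < _MIN_TAIL:
        raise PowerLawFitError(
            f"only {n} samples in [{x_min}, {x_max}] (< {_MIN_TAIL})", n_tail=n
        )
    mean_log = float(np.mean(np.log(s)))

    def nll(tau):
        e = 1.0 - tau
        if abs(e) < 1e-9:
            norm = math.log(math.log(x_max / x_min))
        else:
            norm = math.log((x_max**e - x_min**e) / e)
        return tau * mean_log + norm

    res = minimize_scalar(nll, bounds=(1.000001, 6.0), method="bounded")
    tau = float(res.x)
    ss = np.sort(s)
    emp = np.arange(1, n + 1) / n
    ks = float(np.max(np.abs(emp - _trunc_cdf(ss, tau, x_min, x_max))))
    return PowerLawFit(exponent=tau, x_min=float(x_min), x_max=float(x_max),
                       n_tail=n, ks_distance=ks)


def sample_truncated_powerlaw(
    exponent: float, x_min: float, x_max: float, n: int, seed: int
) -> np.ndarray:
    """Exact inverse-CDF sampler for the truncated power law (test oracle
    and fixture generator)."""
    u = np.random.default_rng(seed).random(n)
    e = 1.0 - exponent
    if abs(e) < 1e-12:
        return x_min * (x_max / x_min) ** u
    return (x_min**e + u * (x_max**e - x_min**e)) ** (1.0 / e)


@dataclass
class CracklingResult:
    gamma_fit: float
    gamma_pred: float
    consistent: bool
    r_squared: float
    n_bins: int


def crackling_check(
    catalog: AvalancheCatalog,
    fits: tuple[PowerLawFit, PowerLawFit],
    n_bins: int = 15,
    tolerance: float = 0.15,
) -> CracklingResult:
    """Test the crackling-noise scaling law on a catalog.

    ``fits`` is (size fit, duration fit).  gamma_fit is the log-log slope of
    the mean size conditioned on duration over the duration fit range
    (log-spaced bins, >= 5 events per used bin); gamma_pred is
    (tau_T - 1)/(tau_S - 1).
    """
    size_fit, dur_fit = fits
    lo, hi = dur_fit.x_min, dur_fit.x_max
    m = (catalog.durations >= lo) & (catalog.durations <= hi)
    T, S = catalog.durations[m], catalog.sizes[m]
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    idx = np.digitize(T, edges)
    mt, ms = [], []
    for b in range(1, n_bins + 1):
        sel = idx == b
        if sel.sum() >= 5:
            mt.append(T[sel].mean())
            ms.append(S[sel].mean())
    if len(mt) < 5:
        raise ValueError(
            f"crackling check needs >= 5 populated duration bins, got {len(mt)}"
        )
    u, v = np.log(mt), np.log(ms)
    slope, intercept = np.polyfit(u, v, 1)
    pred = slope * u + intercept
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum((v - pred) ** 2)) / ss_tot if ss_tot else 1.0
    gamma_pred = (dur_fit.exponent - 1.0) / (size_fit.exponent - 1.0)
    return CracklingResult(
        gamma_fit=float(slope),
        gamma_pred=float(gamma_pred),
        consistent=abs(slope - gamma_pred) < tolerance,
        r_squared=r2,
        n_bins=len(mt),
    )


def default_duration_range(dt: float, total_duration: float) -> tuple[float, float]:
    """Default duration fitting range [10*dt, 0.1*total]: above the
    discreteness floor, below the censoring scale of a single run."""
    return 10.0 * dt, 0.1 * total_duration


def induced_size_range(D: float, t_range: tuple[float, float]) -> tuple[float, float]:
    """Size range induced by a duration range via the Brownian area scale
    s(T) = sqrt(2 D) * T^{3/2} (unit prefactor)."""
    amp = math.sqrt(2.0 * D)
    return amp * t_range[0] ** 1.5, amp * t_range[1] ** 1.5
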