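"""Euler–Maruyama integration of normal-form Langevin equations.

The model is ``dx = f(x, mu) dt + sqrt(2 D dt) z_k`` with ``z_k`` standard
normal, i.e. additive Gaussian white noise of standard deviation
``sigma = sqrt(2D)``.  Ensembles use a seed ladder (seed, seed+1, ...): every
repeat draws from its own ``numpy.random.Generator``, so a member of an
ensemble is bit-identical to a standalone run with the same seed, and repeats
are independent by construction.

Divergence (fly-away regimes of the subcritical and saddle-type forms) is a
legitimate outcome, not an error: a trajectory whose state leaves
``|x| < 1e6`` or becomes non-finite is truncated at its last finite recorded
sample and flagged ``diverged`` in its metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .forms import NormalForm, drift_coefficients, tracked_fixed_point

__all__ = [
    "SimConfig",
    "PerturbationProtocol",
    "Trajectory",
    "simulate",
    "simulate_many",
    "ensemble",
    "apply_constraint",
]

_DIVERGE_LIMIT = 1e6
_BLOCK = 4096  # steps of pre-drawn noise per chunk (bounds memory)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one stochastic experiment.

    dt and durations are in seconds; D is the diffusion constant (noise
    standard deviation sigma = sqrt(2D)); ``settle_time`` seconds are
    integrated and discarded before measurement starts; ``record_stride``
    thins the recorded samples (the integration step stays dt).
    """

    duration: float
    dt: float = 1e-3
    D: float = 0.0
    x0: float = 0.0
    settle_time: float = 0.0
    seed: int = 0
    record_stride: int = 1

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.settle_time < 0:
            raise ValueError("settle_time must be non-negative")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass(frozen=True)
class PerturbationProtocol:
    """Instantaneous pulses applied during the measurement window.

    ``pulse_times`` are seconds relative to the end of settling; each pulse
    increments the state by the paired amplitude (a single amplitude is
    broadcast over all pulse times).  ``n_repeats`` sets the ensemble size.
    """

    amplitudes: Sequence[float]
    pulse_times: Sequence[float] = (0.0,)
    n_repeats: int = 1

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        na, nt = len(self.amplitudes), len(self.pulse_times)
        if na not in (1, nt) and nt not in (1, na):
            raise ValueError("amplitudes and pulse_times lengths incompatible")

    def schedule(self, dt: float) -> list[tuple[int, float]]:
        """(step index, amplitude) pairs on the integration grid."""
        amps = list(self.amplitudes)
        times = list(self.pulse_times)
        if len(amps) == 1:
            amps = amps * len(times)
        if len(times) == 1:
            times = times * len(amps)
        return sorted((int(round(t / dt)), a) for t, a in zip(times, amps))


@dataclass
class Trajectory:
    """A uniformly sampled scalar time series plus its provenance."""

    t: np.ndarray
    x: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else math.nan

    @property
    def diverged(self) -> bool:
        return bool(self.meta.get("diverged", False))


def apply_constraint(x, form: NormalForm):
    """Apply the form's state constraint (reflecting boundaries).

    ``positive_only`` reflects at 0; ``within_basin`` reflects at the basin
    border (x = 0) of the tracked stable fixed point when mu > 0, and is a
    no-op when the origin itself is tracked (mu <= 0).
    """
    if form.constraint == "positive_only":
        return np.abs(x) if isinstance(x, np.ndarray) else abs(x)
    if form.constraint == "within_basin" and form.mu > 0:
        return np.abs(x) if isinstance(x, np.ndarray) else abs(x)
    return x


def _reflecting(form: NormalForm) -> bool:
    return form.constraint == "positive_only" or (
        form.constraint == "within_basin" and form.mu > 0
    )


def simulate_many(
    form: NormalForm,
    config: SimConfig,
    protocol: Optional[PerturbationProtocol],
    seeds: Sequence[int],
    amplitude_scale: Optional[np.ndarray] = None,
) -> list[Trajectory]:
    """Integrate one condition for several seeds at once.

    The repeats are advanced in lock-step with per-seed noise streams, which
    is fast (vectorized across repeats) yet bit-identical to running each
    seed on its own.  ``amplitude_scale`` optionally multiplies every pulse
    amplitude per repeat (used to run mixed-amplitude trial blocks).
    """
    W = len(seeds)
    dt = config.dt
    n_settle = int(round(config.settle_time / dt))
    n = int(round(config.duration / dt))
    stride = config.record_stride
    sig = math.sqrt(2.0 * config.D * dt)
    a0, a1, c, npow = drift_coefficients(form)
    reflect = _reflecting(form)
    cube = npow == 3

    pulses = dict(protocol.schedule(dt)) if protocol is not None else {}
    if amplitude_scale is not None:
        amplitude_scale = np.asarray(amplitude_scale, dtype=float)
        if amplitude_scale.shape != (W,):
            raise ValueError("amplitude_scale must have one entry per seed")
    for step in pulses:
        if not (0 <= step <= n):
            raise ValueError("pulse time outside the measurement window")

    gens = [np.random.default_rng(int(s)) for s in seeds]
    x = np.full(W, config.x0, dtype=float)
    alive = np.ones(W, dtype=bool)

    def _pulse(step_idx: int):
        if step_idx in pulses:
            amp = pulses[step_idx]
            if amplitude_scale is None:
                x[alive] += amp
            else:
                x[alive] += amp * amplitude_scale[alive]

    def _advance(nsteps: int, rec: Optional[np.ndarray], offset: int):
        """Advance all live repeats nsteps; record strided samples."""
        done = 0
        while done < nsteps:
            b = min(_BLOCK, nsteps - done)
            noise = None
            if sig > 0.0:
                noise = np.empty((W, b))
                for i, g in enumerate(gens):
                    noise[i] = g.standard_normal(b)
            with np.errstate(over="ignore", invalid="ignore"):
                for j in range(b):
                    if cube:
                        dx = (a1 * x - c * (x * x * x)) * dt
                    elif npow == 2:
                        dx = (a0 + a1 * x - c * (x * x)) * dt
                    else:
                        dx = (a1 * x) * dt
                    if noise is not None:
                        x[:] = x + dx + sig * noise[:, j]
                    else:
                        x[:] = x + dx
                    if reflect:
                        np.abs(x, out=x)
                    if rec is not None:
                        k = offset + done + j
                        _pulse(k + 1)
                        if (k + 1) % stride == 0:
                            rec[(k + 1) // stride] = x
            done += b
            # divergence check per block: freeze runaway repeats as NaN
            bad = ~np.isfinite(x) | (np.abs(x) > _DIVERGE_LIMIT)
            if bad.any():
                x[bad] = np.nan
                alive[bad] = False

    _advance(n_settle, rec=None, offset=-n_settle)

    n_rec = n // stride + 1
    rec = np.empty((n_rec, W))
    _pulse(0)
    rec[0] = x
    _advance(n, rec=rec, offset=0)

    t = np.arange(n_rec) * (dt * stride)
    out = []
    base_meta = {
        "form": form.name,
        "mu": form.mu,
        "D": config.D,
        "dt": dt,
        "record_stride": stride,
        "constraint": form.constraint,
        "x0": config.x0,
        "settle_time": config.settle_time,
    }
    for i, s in enumerate(seeds):
        xi = rec[:, i]
        finite = np.isfinite(xi)
        diverged = not finite.all()
        if diverged:
            last = int(np.argmin(finite))  # first non-finite recorded sample
            xi = xi[:last]
            ti = t[:last]
        else:
            ti = t
        meta = dict(base_meta, seed=int(s), diverged=diverged)
        out.append(Trajectory(t=ti, x=xi.copy(), meta=meta))
    return out


def simulate(
    form: NormalForm,
    config: SimConfig,
    protocol: Optional[PerturbationProtocol] = None,
) -> Trajectory:
    """Integrate a single seeded trajectory of the form under ``config``."""
    return simulate_many(form, config, protocol, [config.seed])[0]


def ensemble(
    form: NormalForm,
    config: SimConfig,
    protocol: Optional[PerturbationProtocol] = None,
) -> list[Trajectory]:
    """``n_repeats`` trajectories with seeds seed, seed+1, ...

    With D = 0 all repeats are identical; with D > 0 they are independent
    realizations of the same condition.
    """
    n_rep = protocol.n_repeats if protocol is not None else 1
    seeds = [config.seed + i for i in range(n_rep)]
    return simulate_many(form, config, protocol, seeds)


def relaxation_ensemble(
    form: NormalForm,
    delta: float,
    n_repeats: int,
    config: SimConfig,
) -> list[Trajectory]:
    """Convenience: settle at the tracked fixed point, pulse by ``delta`` at
    t = 0, and record the relaxation for ``config.duration`` seconds."""
    xstar = tracked_fixed_point(form)
    cfg = SimConfig(
        duration=config.duration,
        dt=config.dt,
        D=config.D,
        x0=xstar,
        settle_time=config.settle_time,
        seed=config.seed,
        record_stride=config.record_stride,
    )
    proto = PerturbationProtocol(amplitudes=[delta], pulse_times=[0.0],
                                 n_repeats=n_repeats)
    return ensemble(form, cfg, proto)
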