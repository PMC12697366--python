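"""Exact synthetic datasets with known ground truth.

These generators back the unit tests and the ``critbif fixture`` command:
an inverse-CDF truncated power-law sampler, analytic decay series, a seeded
driftless random walk, and the closed-form solution of the critical
supercritical pitchfork, x' = -x^3:

    x(t) = x0 / sqrt(1 + 2 x0^2 t),

which approaches the universal asymptote (2t)^{-1/2} independent of x0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .avalanches import sample_truncated_powerlaw

__all__ = [
    "closed_form_pitchfork",
    "exponential_series",
    "brownian_walk",
    "power_law_samples",
    "make_fixture",
]

FIXTURE_KINDS = (
    "power_law_samples",
    "exponential_series",
    "brownian_walk",
    "closed_form_pitchfork",
)


def closed_form_pitchfork(t, x0: float = 5.0) -> np.ndarray:
    """Exact solution of the critical pitchfork drift x' = -x^3."""
    t = np.asarray(t, dtype=float)
    out = x0 / np.sqrt(1.0 + 2.0 * x0**2 * t)
    return out if out.ndim else float(out)


def exponential_series(t, tau: float = 1.0, amplitude: float = 1.0) -> np.ndarray:
    """Analytic exponential decay amplitude * exp(-t / tau)."""
    t = np.asarray(t, dtype=float)
    return amplitude * np.exp(-t / tau)


def brownian_walk(n: int, dt: float, D: float, seed: int) -> np.ndarray:
    """Driftless random walk x_{k+1} = x_k + sqrt(2 D dt) z_k from x_0 = 0."""
    g = np.random.default_rng(seed)
    steps = np.sqrt(2.0 * D * dt) * g.standard_normal(n)
    out = np.empty(n + 1)
    out[0] = 0.0
    np.cumsum(steps, out=out[1:])
    return out


def power_law_samples(
    exponent: float, n: int, seed: int,
    x_min: float = 1.0, x_max: float = 1e4,
) -> np.ndarray:
    """Exact truncated-power-law samples via the inverse CDF."""
    return sample_truncated_powerlaw(exponent, x_min, x_max, n, seed)


def make_fixture(kind: str, params: dict, seed: int = 0, path=None):
    """Build a synthetic dataset and optionally write it as CSV.

    Returns the array (and writes a one/two-column CSV when ``path`` is
    given).  Identical (kind, params, seed) always produce identical data.
    """
    params = dict(params)
    if kind == "power_law_samples":
        data = power_law_samples(seed=seed, **params)
        frame = pd.DataFrame({"sample": data})
    elif kind == "exponential_series":
        t = np.arange(params.pop("n", 1000)) * params.pop("dt", 1e-2)
        data = exponential_series(t, **params)
        frame = pd.DataFrame({"t": t, "x": data})
    elif kind == "brownian_walk":
        data = brownian_walk(seed=seed, **params)
        t = np.arange(len(data)) * params.get("dt", 1e-3)
        frame = pd.DataFrame({"t": t, "x": data})
    elif kind == "closed_form_pitchfork":
        t = np.arange(params.pop("n", 1000)) * params.pop("dt", 1e-2)
        data = closed_form_pitchfork(t, **params)
        frame = pd.DataFrame({"t": t, "x": data})
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if path is not None:
        frame.to_csv(Path(path), index=False)
    return data
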