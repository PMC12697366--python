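"""Stimulus–response mutual information from stochastic ensembles.

A pulse perturbation delta_X is applied to the settled system and the state
X_tau is recorded at later lags tau.  The information the state retains
about the stimulus is

    I(X_tau; delta_X) = H(X_tau) - H(X_tau | delta_X)      [bits]

with plug-in (histogram) Shannon entropies estimated from the ensemble of
trials, sharing one set of equal-width bin edges across all stimulus
conditions at a given lag (default: 32 bins spanning the pooled 1st–99th
percentile range).  Because the edges are shared, the plug-in I is the
mutual information of the empirical joint distribution and is therefore
non-negative and bounded by log2(number of distinct stimuli).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import PerturbationProtocol, SimConfig, Trajectory, simulate_many
from .forms import NormalForm, tracked_fixed_point

__all__ = [
    "DEFAULT_DELTAS",
    "DEFAULT_LAGS",
    "MITrialTable",
    "MIResult",
    "run_mi_trials",
    "entropy",
    "mutual_information",
    "mi_sweep",
]

log = logging.getLogger(__name__)

#: Pulse amplitudes of the stimulus set, in order-parameter units.
DEFAULT_DELTAS = (0.05, 0.1, 0.2, 0.3, 0.5, 1.0)
#: Readout lags in seconds.
DEFAULT_LAGS = tuple(float(k) for k in range(1, 20))

MIN_CELL_TRIALS = 30


@dataclass
class MITrialTable:
    """Long-format trial records: one row per (trial, lag) with the applied
    pulse ``delta`` and the state ``x_tau`` at that lag."""

    data: pd.DataFrame  # columns: trial, delta, lag, x_tau
    meta: dict = field(default_factory=dict)

    @property
    def deltas(self) -> np.ndarray:
        return np.sort(self.data["delta"].unique())

    @property
    def lags(self) -> np.ndarray:
        return np.sort(self.data["lag"].unique())


@dataclass
class MIResult:
    """Mutual information and entropies per lag for one condition."""

    table: pd.DataFrame  # columns: lag, mi_bits, h_bits, hcond_bits
    mu: float
    form: str
    n_bins: int
    meta: dict = field(default_factory=dict)


def run_mi_trials(
    form: NormalForm,
    config: SimConfig,
    delta_set: Sequence[float] = DEFAULT_DELTAS,
    lags: Sequence[float] = DEFAULT_LAGS,
    n_trials: int = 500,
) -> MITrialTable:
    """Run pulse–readout trials, allocated round-robin over ``delta_set``.

    Trial i uses seed ``config.seed + i`` and pulse ``delta_set[i % K]``
    (500 trials over 6 deltas -> 83 or 84 each).  Each trial settles at the
    tracked fixed point for ``config.settle_time``, is pulsed at t = 0, and
    its state is read at every lag.  Diverged trials are excluded; more than
    10% exclusions is an error.
    """
    lags = np.asarray(sorted(lags), dtype=float)
    K = len(delta_set)
    xstar = tracked_fixed_point(form)
    stride = config.record_stride
    dt = config.dt
    lag_idx = np.round(lags / (dt * stride)).astype(int)
    if np.any(np.abs(lag_idx * dt * stride - lags) > 1e-9):
        raise ValueError("lags must lie on the recorded time grid")
    cfg = SimConfig(duration=float(lags[-1]), dt=dt, D=config.D, x0=xstar,
                    settle_time=config.settle_time, seed=config.seed,
                    record_stride=stride)
    rows = []
    n_diverged = 0
    for j, delta in enumerate(delta_set):
        trial_ids = list(range(j, n_trials, K))
        seeds = [config.seed + i for i in trial_ids]
        proto = PerturbationProtocol(amplitudes=[float(delta)],
                                     pulse_times=[0.0])
        trajs = simulate_many(form, cfg, proto, seeds)
        for tid, tr in zip(trial_ids, trajs):
            if tr.diverged:
                n_diverged += 1
                continue
            rows.append(
                pd.DataFrame({
                    "trial": tid,
                    "delta": float(delta),
                    "lag": lags,
                    "x_tau": tr.x[lag_idx],
                })
            )
    if n_diverged > 0.1 * n_trials:
        raise RuntimeError(
            f"{n_diverged}/{n_trials} trials diverged (>10%)"
        )
    if n_diverged:
        log.warning("run_mi_trials: excluded %d diverged trials", n_diverged)
    data = pd.concat(rows, ignore_index=True)
    meta = {
        "form": form.name, "mu": form.mu, "D": config.D,
        "constraint": form.constraint, "n_trials": n_trials - n_diverged,
        "seed": config.seed, "settle_time": config.settle_time,
        "x_star": xstar,
    }
    return MITrialTable(data=data, meta=meta)


def entropy(samples: Sequence[float], bins) -> float:
    """Plug-in Shannon entropy (bits) of a histogram of ``samples``.

    ``bins`` is either an integer count (equal-width over the sample range)
    or an explicit edge array; empty bins contribute 0.  A single bin is a
    degenerate discretization and returns 0 bits with a warning.
    """
    s = np.asarray(samples, dtype=float)
    if len(s) < 2:
        raise ValueError("entropy needs at least 2 samples")
    if np.isscalar(bins) and int(bins) == 1:
        warnings.warn("degenerate binning (1 bin): entropy is 0 bits")
        return 0.0
    counts, _ = np.histogram(s, bins=bins)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _shared_edges(x: np.ndarray, n_bins: int,
                  bin_range: Optional[tuple[float, float]]) -> np.ndarray:
    if bin_range is None:
        lo, hi = np.percentile(x, [1.0, 99.0])
        if hi <= lo:
            lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1e-12
    else:
        lo, hi = bin_range
    return np.linspace(lo, hi, n_bins + 1)


def mutual_information(
    table: MITrialTable,
    n_bins: int = 32,
    bin_range: Optional[tuple[float, float]] = None,
) -> MIResult:
    """Plug-in I(X_tau; delta_X) per lag from an MI trial table.

    Bin edges are shared across all stimulus conditions at each lag (equal
    width over the pooled 1st–99th percentile range unless ``bin_range``
    pins them).  H is the entropy of the pooled readout; the conditional
    entropy weights each stimulus by its empirical allocation.  Cells with
    fewer than 30 trials are excluded with a warning.
    """
    recs = []
    for lag, grp in table.data.groupby("lag", sort=True):
        counts = grp.groupby("delta")["x_tau"].count()
        ok = counts[counts >= MIN_CELL_TRIALS].index
        if len(ok) < len(counts):
            warnings.warn(
                f"lag {lag}: excluded {len(counts) - len(ok)} stimulus cells "
                f"with < {MIN_CELL_TRIALS} trials"
            )
        if len(ok) < 2:
            continue
        sub = grp[grp["delta"].isin(ok)]
        pooled = sub["x_tau"].to_numpy()
        edges = _shared_edges(pooled, n_bins, bin_range)
        h = entropy(pooled, edges)
        h_cond = 0.0
        for delta, cell in sub.groupby("delta"):
            w = len(cell) / len(sub)
            h_cond += w * entropy(cell["x_tau"].to_numpy(), edges)
        recs.append({"lag": float(lag), "mi_bits": h - h_cond,
                     "h_bits": h, "hcond_bits": h_cond})
    res = pd.DataFrame(recs)
    return MIResult(table=res, mu=table.meta.get("mu", math.nan),
                    form=table.meta.get("form", "?"), n_bins=n_bins,
                    meta=dict(table.meta))


def mi_sweep(
    form_name: str,
    mu_grid: Sequence[float],
    config: SimConfig,
    delta_set: Sequence[float] = DEFAULT_DELTAS,
    lags: Sequence[float] = DEFAULT_LAGS,
    n_trials: int = 500,
    constraint: Optional[str] = None,
    n_bins: int = 32,
) -> pd.DataFrame:
    """Sweep the control parameter and tabulate MI/entropies per (mu, lag).

    The constraint defaults to the standard setting for each system:
    within-basin for the pitchfork (avoids metastable hopping between the
    two branches), x > 0 for transcritical and saddle-node (avoids runaway
    through the unstable side), none for the linear form.
    """
    from .forms import normal_form

    if constraint is None:
        constraint = {
            "pitchfork_super": "within_basin",
            "transcritical": "positive_only",
            "saddle_node": "positive_only",
        }.get(form_name, "none")
    frames = []
    for mu in mu_grid:
        form = normal_form(form_name, mu=mu, constraint=constraint)
        tab = run_mi_trials(form, config, delta_set, lags, n_trials)
        res = mutual_information(tab, n_bins=n_bins)
        df = res.table.copy()
        df.insert(0, "mu", float(mu))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "form", form_name)
    return out
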