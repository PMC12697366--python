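# Methods

## Model

All dynamics are one-dimensional Langevin equations

    dx = f(x, mu) dt + sqrt(2 D dt) z_k,   z_k ~ N(0, 1) i.i.d.,

with the drift one of seven canonical normal forms (bifurcation at
`mu = 0` in every case):

| form            | f(x, mu)      | n | c  | leading behavior at mu = 0 |
|-----------------|---------------|---|----|-----------------------------|
| linear          | mu x          | – | 0  | no restoring force          |
| saddle_node     | mu − x²       | 2 | +1 | one-sided restoring         |
| transcritical   | mu x − x²     | 2 | +1 | one-sided restoring         |
| pitchfork_super | mu x − x³     | 3 | +1 | symmetric restoring         |
| pitchfork_sub   | mu x + x³     | 3 | −1 | repelling                   |
| hopf_super      | mu r − r³     | 3 | +1 | symmetric restoring (r ≥ 0) |
| hopf_sub        | mu r + r³     | 3 | −1 | repelling                   |

The nonlinear part is written `−c xⁿ` so `c > 0` is restoring.  The Hopf
forms are reduced to their radial amplitude equation: the oscillation
amplitude is the order parameter and carries all of the scale-invariance
content used here, so the phase variable is omitted.  The subcritical
pitchfork is kept in its unbounded cubic form (no quintic stabilization).
The noise amplitude is `sigma = sqrt(2D)`, the standard
fluctuation–dissipation convention relating `sigma` to the diffusion
constant `D`.

Two derived scales organize the analysis, both implemented with unit
proportionality constants since they are order-of-magnitude balances:
`xi_lin = (|mu|/|c|)^{1/(n−1)}` (linear vs nonlinear drift; for the
saddle-node the "linear" term is the constant offset `mu`, and the same
uniform formula is used) and `xi_noise = (D/|c|)^{1/(n+1)}` (drift vs
diffusion).  The linear form reports `xi_lin = inf` and `xi_noise = NaN`.

## Integration

Explicit Euler–Maruyama with default `dt = 1e-3` s (`1e-4` for
deterministic closed-form comparisons), the standard scheme for additive
noise.  Ensembles use a seed ladder: repeat `i` draws from
`default_rng(seed + i)`, so each member is bit-identical to a standalone
run with that seed while the ensemble is advanced vectorized in lock-step
(noise pre-drawn in blocks; NumPy `Generator` streams are identical
whether drawn singly or in blocks).  Pulses are applied instantaneously at
their grid sample.  State constraints are reflecting walls applied after
every step: `positive_only` reflects at 0; `within_basin` reflects at the
basin border (x = 0) of the tracked upper fixed point when `mu > 0` and is
a no-op otherwise.  Reflection (rather than absorbing walls or trial
rejection) preserves trial counts and local dynamics near the fixed point.
Trajectories whose state leaves `|x| < 1e6` (or turns non-finite) are
truncated at the last finite recorded sample and flagged `diverged` —
fly-away is data, not an error, because it is exactly what the taxonomy
predicts for the non-robust forms.

Weak convergence was checked by dt-halving on the strong-pulse ensemble
(mean response changes < 2%), and the noise calibration by the Brownian
variance law Var = 2Dt and the Ornstein–Uhlenbeck stationary variance
D/|mu| (both within 10% at Monte-Carlo scale in the test suite).

## Relaxation fitting

A relaxation curve is the ensemble mean of the signed displacement
`x − x*` from the tracked fixed point, aligned at the pulse; diverged
repeats are excluded (error if more than half).  Fits are ordinary least
squares on the linearizing axes (log response vs log lag for a power law;
log response vs lag for an exponential), never taking logs of non-positive
samples (windows auto-shrink at the first non-positive mean).

Default fit windows are theory-derived rather than fixed fractions of the
record:

* power law: from the lag where the mean response first falls to half the
  pulse amplitude (discarding the initial plateau, which still remembers
  `delta_x` rather than the universal decay) down to the crossover scale —
  `xi_noise` for noisy runs, `xi_lin` for deterministic ones;
* exponential: from where the response falls below
  `min(delta_x, xi_lin/3)` (linearization error of order
  `(x/xi_lin)^{n−1} ≲ 10%`) down to the ensemble noise floor, taken as 3×
  the median standard error of the mean.  The *mean* of a noisy linear
  relaxation stays exponential below `xi_noise` (the fluctuations average
  out across repeats), so the exponential window deliberately extends
  beyond the single-trial Brownian floor.

Both windows are explicit parameters; every reported fit carries its
window, point count and r².  Regime classification splits a curve where
the response crosses the relevant `xi`, labels the sub-`xi_noise` segment
of noisy runs `noise_floor`, and otherwise assigns each segment to the
transform with the higher r².

## Avalanches

An avalanche is a maximal run of samples strictly above a threshold;
duration is the run length times the sampling interval and size the
integrated excess area.  Runs touching either end of a record are dropped
(censored), and independent runs of one condition are pooled as catalogs,
never as concatenated series (a seam would fabricate crossings).  The
default threshold is the tracked fixed point; for forms confined by a
reflecting wall at 0 the survey thresholds at the pooled sample median
instead, since the state never crosses the wall level.

Exponents come from continuous maximum likelihood for a power law
truncated to `[x_min, x_max]` (bounded scalar minimization of the exact
negative log-likelihood), with a KS distance on the fit range and a
minimum of 50 in-range events.  Defaults: durations on
`[10·dt, 0.1·run length]` (above the discreteness floor, below the
censoring scale); sizes on the range induced through the Brownian area
scale `s(T) = sqrt(2D)·T^{3/2}`.  The crackling check regresses mean size
on duration over log-spaced bins (≥ 5 events per bin, ≥ 5 bins) and
compares the slope with `(tau_T − 1)/(tau_S − 1)` at tolerance 0.15.

## Mutual information

Trials allocate the six pulse amplitudes {0.05, 0.1, 0.2, 0.3, 0.5, 1}
round-robin (so 500 trials give 83–84 per amplitude), settle at the
tracked fixed point (default 100 s), pulse at t = 0, and read the state at
integer-second lags 1–19.  Entropies are plug-in histogram estimates with
equal-width bins shared across all stimulus conditions at a lag (default
32 bins spanning the pooled 1st–99th percentile range; the bin policy is a
parameter because it is the one materially unstated estimation choice).
Shared edges make the plug-in mutual information the MI of the empirical
joint — non-negative and bounded by log2(#stimuli) — and make nested bin
counts obey the data-processing inequality exactly.  No bias correction is
applied by default (the plug-in estimator is reported as defined); the
positive small-sample bias is roughly `(bins−1)(stimuli−1)/(2N ln 2)` and
cancels in the within-sweep comparisons the package makes.  Cells with
fewer than 30 trials are excluded with a warning; cross-*system* entropy
comparisons use a pinned absolute bin range, since percentile-adaptive
bins are only comparable within one condition.

## Synthetic data and what the tests show

All test inputs are generated in-process: seeded normal-form simulations,
driftless random walks, inverse-CDF truncated-power-law samples, and the
closed-form solution `x(t) = x0/sqrt(1 + 2 x0² t)` of the critical cubic
decay.  The generators emulate the study conditions (D = 5e-5, pulses of
0.5 and 5 `xi_noise`, 200-repeat ensembles, 100 s settling, 10 pooled
runs) but not features of real recordings — measurement noise, drifting
parameters, non-stationarity, discreteness of spike counts — so passing
tests certify the estimators and the normal-form theory, not performance
on empirical data.  Problem sizes in the suite are the package's own
desk-scale choices: avalanche runs of 10 × 10⁶ steps; MI-peak sweeps with
300 trials, 30 s settling and lags to 10 s; the D^{1/4} spread scaling at
`dt = 5e-3` with settle/measure of 3/10 nonlinear relaxation times
(`tau ~ D^{-1/2}`) per noise level.

## Known limitations

* Hopf forms carry no phase dynamics, so oscillatory ringing in relaxation
  is out of scope; the classifier only sees the amplitude.
* Explicit Euler–Maruyama needs `dt · |f'(x)|` well below 1; kicks far
  beyond `xi_lin` at coarse `dt` can destabilize (the demo uses
  `dt ≤ 5e-3` for `x0 = 5`).
* Continuous MLE applied to durations quantized at `dt` biases exponents
  near the discreteness floor; the default `x_min = 10·dt` keeps the bias
  within the tolerances used here.
* The plug-in MI estimator's bias grows with bin count and shrinks with
  trials; absolute MI values should not be compared across different bin
  policies.
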