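# Methods

`eegconn` implements a windowed multivariate-autoregressive (MVAR) analysis
of multichannel EEG component signals, four directed connectivity
estimators used as classification features, a periodogram baseline, and a
tuned RBF-SVM comparison of two experimental conditions. Because the kind
of recordings it targets are typically not redistributable, the package
ships a synthetic-data module that generates ground-truth MVAR systems with
known directed coupling; every quantitative claim the test suite and the
acceptance script make is computed on such systems.

## Signal model

Each analysis window of a `k`-channel epoch is modeled as a zero-mean,
stationary MVAR(p) process

    X(t) = Σ_{j=1..p} A(j) X(t−j) + E(t),

with `A(j)` the `k × k` lag-`j` coefficient matrix (indexed
target × source) and `E(t)` white innovations with covariance `V`.
Windows are short (400 ms by default), so local stationarity is assumed
per window and the window mean is removed before fitting (the model has no
intercept). Coefficients are estimated by ordinary least squares on the
stacked lagged regression; the residual covariance uses the unbiased
divisor `n_obs − k·p` (with `n_obs = window_samples − p`), while the
information criteria below use the maximum-likelihood divisor `n_obs`,
the standard convention. OLS was chosen over lattice (Vieira–Morf-style)
estimators for transparency: it admits exact small-sample oracles
(normal-equation solves, deterministic recursions) and matches
`statsmodels`' VAR on identical inputs to 1e−8, which the test suite
verifies. The estimator is a single function and can be swapped.

## Analysis geometry

The study protocol this pipeline reproduces uses six component signals
(frontal, central, parietal, occipital, left motor, right motor) at
250 Hz; non-distracted epochs last 1200 ms (300 samples) and distracted
epochs 1600 ms (400 samples). Epochs are divided into 400 ms windows
advanced in 50 ms steps. At 250 Hz the step is 12.5 samples; the window
count uses the exact fractional step,
`floor((N − L)/step) + 1`, which yields the canonical 17 windows per
non-distracted and 25 per distracted epoch; integer start samples are the
rounded multiples of the fractional step, so consecutive starts alternate
between 12 and 13 samples. Incomplete trailing windows are discarded.
All window intervals are half-open, 0-based.

## Model-order selection

Four criteria are computed per window and averaged over windows and
epochs, for orders 1..p_max:

    SBC = ln det V̂ + ln(n)·p·k²/n
    AIC = ln det V̂ + 2·p·k²/n
    HQ  = ln det V̂ + 2·ln(ln n)·p·k²/n
    FPE = det V̂ · ((n + p·k + 1)/(n − p·k − 1))^k

with `n = n_obs` (which varies with `p`). Two read-outs are provided:
the curve minimum (smallest order on ties) and the "elbow", defined as
the interior point of maximal perpendicular distance from the chord
joining the curve's first and last points — a deterministic,
parameter-free formalisation; on a straight curve the smallest interior
order wins. With OLS, `p_max` is limited by window identifiability
(`n_obs > k·p + k − p`): on 400 ms windows of 6 channels this caps
`p_max` near 13, so exploring orders up to 30 requires longer windows.
The pipeline default order is 5.

## Connectivity estimators

From each window's fit, the coefficient spectrum is

    A̅(f) = I − Σ_{r=1..p} A(r) e^{−i2πfr/fs},

and the transfer matrix `H(f) = A̅(f)⁻¹`. All tensors are indexed
`source × target × frequency × window`, on the integer grid 1..20 Hz
by default:

* **DTF**: `dtf(s→t, f) = |H_ts|² / Σ_m |H_tm|²`. Normalised over all
  inflows into the target: the tensor sums to one over the source axis.
* **PDC**: `pdc(s→t, f) = |A̅_ts|² / Σ_m |A̅_ms|²`. Normalised over the
  source's outflows: sums to one over the target axis. The squared-
  magnitude convention is used so both spectral estimators (and GPDC) are
  on the same [0, 1] power-like scale.
* **GPDC**: PDC with inverse-innovation-variance weights,
  `(|A̅_ts|²/σ_t²) / Σ_m (|A̅_ms|²/σ_m²)` — invariant to per-channel
  amplitude scaling; equals PDC when variances are equal.
* **GGC** (Granger–Geweke index, time domain):
  `ln(var_t without s / var_t full)`, where the reduced model refits the
  window with the candidate source channel removed (conditional on all
  remaining channels). Negative finite-sample values are floored at zero
  and the diagonal is zero. The index has no frequency dependence; it is
  replicated across the 20 frequency bins so all four estimators share
  the same 4-D tensor shape (a spectral Geweke decomposition is a
  possible extension, not implemented).

The same spectral kernel evaluates the *true* coefficients of a synthetic
system, giving a closed-form oracle (`true_spectral_connectivity`) that
never touches data. Estimates from a 2×10⁴-sample realisation of the
6-channel fixture systems agree with the oracle within 0.05 sup-norm over
all (source, target, frequency) cells; single 10⁴-sample realisations
have sup-norm sampling tails slightly above that, which is why the
validation size is 2×10⁴.

## PSD baseline

Per channel, the plain (rectangular-window) one-sided periodogram
`Δt/N |Σ x_n e^{−j2πfΔtn}|²` with FFT length the next power of two at or
above the epoch length — 512 for both 300- and 400-sample epochs, giving
6 × 257 = 1542 features per epoch. No tapering, Welch averaging or
band summarisation.

## Preprocessing

The band-pass stage (default 0.5–50 Hz) uses 4th-order Butterworth
low-pass and high-pass cascades, each applied forward-backward
(`sosfiltfilt`) for an exactly zero-phase response — phase distortion
would bias directed estimators. A linear-phase FIR design was rejected
because a 0.5 Hz edge at 250 Hz needs a kernel longer than the 300-sample
epochs this pipeline processes. The low-pass runs before the high-pass so
strong out-of-band energy is removed before the long-time-constant
high-pass sees the epoch edges, and symmetric ("even") edge padding is
used; with odd (default) padding, reflection transients of out-of-band
components leak ~10% of their RMS into the output, versus <1% with this
arrangement. Resampling is polyphase (`resample_poly`) with the rational
rate ratio, output truncated to `floor(n·target_fs/fs)` samples.

## Synthetic data and the default contrast fixture

`make_var_system` builds stationary systems from an explicit directed edge
list (coefficients indexed target × source; self-dynamics from a per-lag
diagonal profile). Requested coefficient sets whose companion spectral
radius reaches 1 are uniformly shrunk (same factor, all lags) until the
radius is ≤ 0.98, and the factor is reported — construction stays
deterministic. Innovations are multivariate Gaussian (the standard MVAR
assumption; nothing in the target data argues otherwise), epochs are
drawn independently with a 500-sample burn-in (hundreds of times the
default order's memory).

The default two-condition fixture emulates the study geometry (six
channels, 250 Hz, 1200/1600 ms epochs, several subjects with independent
realisations) with a *directional* contrast:

* non-distracted: a directed ring over the six components, strength 0.35;
* distracted: the same ring reversed, plus two extra chords
  (central→left-motor, parietal→right-motor, strength 0.25) — a denser
  graph, consistent with the qualitative observation that brain networks
  densify under distraction;
* identical damped-oscillation self-dynamics
  (0.55, −0.25, 0.15, −0.10, 0.05 across lags 1–5) on every channel, and
  the distracted system's innovation variances rescaled (fixed-point on
  the companion-form Lyapunov solution) so stationary per-channel power
  is identical across conditions.

The reversal + power matching matter: they place the condition contrast
in directed coupling structure — the quantity connectivity estimators
measure — rather than in per-channel amplitude or spectral shape, which a
periodogram sees equally well. On this fixture PDC features classify
near-perfectly while PSD features perform modestly above chance,
echoing the ordering reported for real recordings without claiming its
percentages. What passing these tests does *not* show: robustness to
nonstationarity within windows, volume conduction/mixing, artifacts,
non-Gaussian innovations, or subject heterogeneity — none of which the
generator emulates.

## Classification

Features are standardized per column on training statistics only. The
SVM uses the Gaussian kernel `K(x1,x2) = exp(−‖x1−x2‖²/(2σ²))`; the box
constraint C and kernel scale σ are tuned by Bayesian optimisation
(Gaussian-process surrogate with Matérn-5/2 kernel, expected-improvement
acquisition over 256 random candidates per iteration, 8 space-filling
initial draws) of the stratified 5-fold cross-validation loss, with 30
objective evaluations total over log-uniform `[1e−3, 1e3]²`; the best
pair is refit on all training rows. Fold assignment is frozen across
evaluations so the objective is deterministic given the seed. The
train/test split is 50:50 within each (subject, condition) cell, odd
counts favouring training, and training rows are shuffled across
subjects. The per-window scan reuses one split for all windows and
classifies each window's `source × target × frequency` block separately;
epochs of unequal duration are aligned to the window indices shared by
both conditions (the leading 17).

## Numerical choices and degenerate inputs

* Ties in order selection resolve to the smallest order.
* Singular window regressions raise an error naming the window.
* GPDC requires strictly positive residual variances; GGC floors
  negative variance-ratio logs at zero.
* The zero-noise simulation limit is supported (PSD-square-root via
  eigendecomposition), producing exactly zero epochs from zero state.
* CV fold counts are reduced to the minority-class size when necessary.
* Connectivity tensors are validated against their normalisation
  invariants (1e−6) on construction in tests; `ConnectivityTensor.validate`
  is available to callers.

## Problem sizes used in validation

Oracle equivalence: one 2×10⁴-sample realisation per estimator. Order
recovery: 20 independent 8000-sample VAR(3) realisations. Null-shrinkage
checks: 500 vs 5000 samples. End-to-end classification: 4 subjects × 5
epochs per class per condition (40 epochs), 30 tuning evaluations;
the PDC-vs-PSD replicate comparison runs 20 seeded replicates in the test
suite and 10 in the acceptance script. These sizes keep the full
validation suite to a few minutes while leaving all statistical margins
wide (order recovery 20/20, edge-recovery AUC 1.0 in development runs).

## Known limitations

* GGC here is the time-domain conditional index; the frequency axis of
  its tensor is replication, not a spectral decomposition.
* OLS limits usable model orders on short windows (see above).
* The EDF reader is a thin optional wrapper (requires `mne`) returning a
  continuous single-epoch container; event-locked epoching of raw
  recordings is the caller's responsibility.
* The synthetic fixture's effect sizes are free design parameters, not
  estimates of any real recording; absolute accuracies on it are not
  comparable to accuracies on real EEG.
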