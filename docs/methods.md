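# Methods

## The model

`wcfield` simulates a Wilson-Cowan neural field: excitatory and inhibitory
firing-rate fields U_e(x, t), U_i(x, t) in [0, 1] obeying

    tau_e dUe/dt = -Ue + F(K_ee*Ue - K_ei*Ui + J_e - b_e)
    tau_i dUi/dt = -Ui + F(K_ie*Ue - K_ii*Ui + J_i - b_i)

with the logistic gain F(u) = 1/(1+e^-u), Gaussian coupling kernels
K_xy(x) = (k_xy / (sigma sqrt(pi))) exp(-x^2/sigma^2) whose spatial integral
is the connection mass k_xy, and external currents J_e, J_i representing
optogenetically induced drive.  The local field potential is the fixed
mixture LFP = 0.8 U_e + 0.2 U_i.  Replacing the kernels by their masses
gives the isolated pair ("point model") used for all bifurcation analysis.

Default constants: k_ee = k_ei = k_ie = 15, k_ii = 7, b_e = 4,
tau_e = 2 ms, tau_i = 4 ms, sigma_e = 0.2 mm, sigma_i = 0.1 mm (excitatory
projections reach twice as far as inhibitory ones), dx = 0.01 mm on a
6 mm domain.  The single qualitative switch is the inhibitory threshold:
b_i = 4 puts the resting pair just below a supercritical Hopf bifurcation
(type II excitability — oscillations born at non-zero frequency with
amplitude growing as sqrt(J_e - J_e*)), while b_i = 8 moves the inhibitory
nullcline onto the middle branch of the excitatory nullcline and the onset
becomes a saddle-node on an invariant circle (type I — period diverging as
(J_e - J_e*)^(-1/2), large amplitude from onset).  Because the currents
enter only through J_i - b_i, injecting J_i = 4 into the b_i = 8 pair is
*exactly* the b_i = 4 pair: focal inhibitory drive converts the medium's
local excitability type, which is the mechanism the package exists to
explore.

## Numerics

* **Integration.** Classical fixed-step RK4 throughout; default dt
  0.01 ms, with a hard guard dt <= min(tau)/10.  The point integrator
  broadcasts over array-valued parameters so entire bifurcation grids run
  as one vectorised pass.  Convergence is genuinely 4th order (the suite
  fits the step-halving slope to 3.5-4.5).
* **Fixed points.** Multi-start root finding (11x11 seed grid over the
  unit square, Powell-hybrid polishing with the analytic 2x2 Jacobian),
  deduplicated at 1e-4.  Roots are accepted on residual (< 1e-10), not on
  the solver's success flag, which misfires when a seed lands exactly on a
  marginal root.
* **Hopf detection.** Bisection on the largest eigenvalue real part of the
  continuously tracked fixed point (parameter tolerance 1e-8); onset
  frequency = |Im lambda| / 2 pi.  A sign change with real eigenvalues, or
  disappearance of the tracked branch, is reported as "no Hopf" — that is
  how the SNIC portion of the onset boundary shows up and why the Hopf
  curve in the (J_e, J_i) plane carries flagged gaps below J_i ~ 3.
  SNIC onsets are located by bisection on the fixed-point count (3 -> 1).
* **Sub/supercritical discrimination** is simulation-based: regression of
  cycle amplitude squared on the parameter excess (supercritical) or of
  period on the inverse square root of the excess (SNIC), plus an up/down
  hysteresis probe with inherited initial conditions that demotes the
  label to "unclassified" if bistability appears.
* **Spatial convolution.** The kernels are truncated at 4 sigma and
  applied by direct discrete convolution scaled by dx; ends are padded
  with the resting rate rather than zero, since the physical background
  outside the domain is the rest state, not silence.  (A zero pad would
  impose a spurious disinhibition gradient at the walls.)  The fast path
  is checked against an O(N M) summation to 1e-10.
* **Absorbing boundaries.** A sponge layer (outer 0.4 mm at each wall)
  adds -lambda(x)(U - U_rest) with lambda ramping linearly from 0 to
  5 /ms.  A periodic mode exists solely so a homogeneous field can be
  verified against the point model node-for-node (agreement 1e-6).

## Wave metrics

Propagation distance is the smallest |x| at which max_t U_e falls below
0.05, averaged over the two sides.  Two deliberate readings of "max over
time" coexist: the *envelope* includes the stimulus-onset response
(stimulation switches on at t = 0 from rest), because the onset wave is
part of the medium's response and is what the regime survey's shaded
envelope records; but a run counts as *indefinite* only if waves are still
reaching the absorbing layer in the final third of the run — a single
escaping onset transient is not indefinite propagation.  A run is "none"
when the envelope stays within half a kernel spread (0.5 sigma_e) of the
stimulus edge; the subthreshold halo of a driven but non-emitting region
only reaches a few hundredths of a millimetre past the stimulus, so this
margin separates halo from emission without being sensitive to its exact
value at the survey's grid resolution.

Mode locking (n:1 emission) counts LFP peaks at the source and at a probe
1.5 mm away over an integer number of *probe* cycles, so a locked ratio is
recovered exactly; a count ratio farther than 0.1 from its nearest integer
is flagged unconfident (irregular emission near regime boundaries does
occur and is deliberately not rounded into a clean label).  Wavefront
speed tracks the LFP upstroke through rest + 0.05 with linear sub-sample
interpolation at the two band edges.

Survey conventions (and why): the regime survey fixes tau_i = 4 ms and
varies tau_e, with focal J_e = 1.3 — the stimulation level of the
space-time panels.  At the alternative level 1.1 the focal region of this
implementation never sustains an oscillation (its Hopf threshold, diluted
by the kernels, sits just above 1.1) and no survey structure exists at
all.  The 1:1 scan uses J_e in {2.0, 2.5, 3.0}, spanning the stimulation
currents used anywhere in the study (ramps end at J_e = 3); with unbounded
drive an irregular near-1:1 can be provoked at slightly lower ratios, but
only the consistently locked count is accepted.

The rescaled beat-skipping configuration multiplies both space constants
by 3 (sigma_e = 0.6, sigma_i = 0.3 mm) *and* the stimulus width
(0.4 -> 1.2 mm) — leaving the stimulus unscaled starves the focal region
through the widened kernels and the 2:1 regime disappears — with
tau_e = 1.8, tau_i = 3.6 ms.  (The transposed assignment tau_e = 3.6,
tau_i = 1.8 produces no oscillation at all; the ratio-2 assignment is the
one used everywhere else in the model.)  Speed is measured from 1 mm
beyond the stimulus edge — waves emerge within about 1 mm of the source —
to the inner edge of the sponge, i.e. the 1.6-2.6 mm band, where the
front has reached its far-field speed (~19 cm/s; fronts accelerate from
~14 cm/s as they detach from the source region).

## Ramp protocol

The ramp drives the point model with J_e linear in time and J_i slaved to
the recruitment law J_i = 8/(1+exp(-beta J_e)) - 4 (odd, saturating at 4 —
the conversion current), preceded by a 500 ms quiet baseline for
spectrogram referencing.  The static critical current on this coupled path
is found by the same eigenvalue bisection.  Two consequences of noiseless
deterministic integration are worth knowing: the oscillation must grow out
of truncation-level perturbations, so the observable up-ramp onset
overshoots the static critical current markedly (slow passage through a
Hopf point), and the overshoot measured in current units shrinks as the
ramp slows (delta-J_e ~ sqrt(ramp rate)) while growing in wall-clock time.
The down-ramp releases close to the static value, so the up/down asymmetry
here is a memory effect, not bistability; with measurement noise the
up-ramp onset would sit much nearer the static point.  Envelope onset is
defined at 5 % of the end-of-ramp envelope — above numerical ripple, far
below the quasi-static branch.  Spectrograms use 256 ms Hann windows with
75 % overlap at the 2 kHz storage rate, reported in dB minus the
per-frequency baseline mean.

## Re-analysis pipeline and what the synthetic data does (and does not) show

The pipeline mirrors a gridded multielectrode analysis: zero-phase
Butterworth band-passing (order chosen by `buttord` for < 1 dB ripple and
> 40 dB stop-band attenuation 20 % beyond the edges, specs halved for the
forward-backward pass), radial averaging into equal-width rings around the
source (empty rings flagged, never interpolated), analytic-signal phase of
the narrowband (reference +/- 4 Hz) source channel, and averaging of the
analysis-band LFP in 24 phase bins per ring.  Beat skipping is quantified
by counting circular local maxima of each ring's phase-binned waveform
(prominence 15 % of its range, half-cycle circular padding).  PSD peaks
use a Welch periodogram against a running-median floor (factor 7, with an
absolute guard against numerically-zero ripple); the factor was calibrated
so white noise yields < 5 % false positives over 100 draws.  Array-level
wave speed regresses cumulative inter-ring cross-correlation delays on
mean ring distance, excluding rings within 0.8 mm of the source where the
source oscillation, not the travelling wave, dominates the band.

The synthetic generator produces the structure this pipeline assumes: a
~100 Hz source of ~0.5 mm footprint emitting a raised-cosine wave cycle on
every n-th source cycle, propagating radially at constant speed with
exponential amplitude decay (1.5 mm), over 1/f plus white noise on a
10 x 10, 0.4 mm-pitch grid at 2 kHz.  It deliberately does *not* model
electrode impedance or referencing, line noise, trial-to-trial source
wander, spatially varying speed, or wavefront curvature effects beyond
pure radial symmetry — so recovery of the generator's parameters
demonstrates that the pipeline is correct and well-conditioned, not that
it would be unbiased on cortical recordings.  Known estimator limits, kept
rather than papered over: with no skipping (n = 1) the source and wave
share one frequency band and residual source leakage biases the speed fit
at high speeds (the 3 x 3 recovery grid accepts 8/9 for exactly this
reason), and on the strongly nonlinear simulated fronts the
cross-correlation (phase-delay) speed reads a few cm/s above the
front-tracking (upstroke) speed — they are different observables on a
non-rigid waveform.

## Problem sizes

Tests and the acceptance script run the field on a coarsened grid
(dx = 0.02 mm, still 5 points per inhibitory kernel sigma) with 300-450 ms
simulations and RK4 steps of 0.02-0.05 ms chosen per run against the
tau/10 guard; the regime survey uses 11 ratio values and the 1:1 scan a
9 x 3 ratio-by-current grid.  Halving dx or dt moves none of the reported
boundaries by more than one grid interval.

## Known limitations

Strictly 1D fields (no spiral or concentric-ring geometry); no conduction
delays, adaptation, or stochastic forcing; limit-cycle envelopes come from
simulation rather than continuation, so extremely slow SNIC cycles need
long settle windows; the Hopf curve is only defined where the onset is a
true Hopf crossing (gaps are reported, not interpolated).
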