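# Methods

`drivevitals` models the signal-processing chain of a non-contact in-cabin
driver monitoring system: capacitive ECG/EEG electrodes embedded in the seat,
a steering-wheel pulse oximeter, and an 8x8 thermopile array, feeding a
five-phase alert state machine with e-Call payload assembly. No real
recordings ship with the package; every stage is specified, exercised and
validated against synthetic signals whose ground truth is known by
construction. This note records the models, the defaults that matter, the
numerical choices, and what the synthetic validation does and does not show.

## Synthetic signal models

**ECG.** Each beat is a sum of Gaussian bumps for the P, Q, R, S and T waves
(offset, amplitude, width per wave), repeated at the requested heart rate
with seeded Gaussian beat-onset jitter (sd 10 ms). Three qualitative
morphology presets are shipped — `normal`, `hypotension` (low-voltage R/T),
`hypertension` (tall R, deep S, flattened T). These encode recognisable
class differences for testing detectors and denoisers; they make no claim of
clinical fidelity. Default sampling rate is 1 kHz (the acquisition rate used
throughout); synthesis requires at least 250 Hz so the QRS is resolved.

**EEG.** An epoch is `alpha + beta + noise`: one sinusoid at a seeded
frequency inside the alpha band (8-12 Hz), one inside beta (14-25 Hz), plus
white Gaussian noise. A pure tone per band is a deliberate simplification —
its peak amplitude equals the configured amplitude exactly, so the
physiological alpha ceiling (5-150 uV, typically 20-50 uV) is respected by
construction and band-power ground truth is analytic (A^2/2 per tone). State
presets fix (alpha, beta, noise) amplitudes in uV: eyes open (10, 20, 5),
eyes closed/relaxed (40, 10, 5), drowsy (60, 8, 5), stress (8, 35, 5),
emotion (25, 18, 5), distraction (12, 15, 25). The alpha-dominant states are
exactly the relaxation/drowsiness ones, mirroring the standard occipital
picture (alpha rises and beta falls as the eyes close and vigilance drops).
Real EEG has 1/f background, spindles and artifacts; none of that is
modelled, so passing tests demonstrate correctness of the analysis chain,
not field performance.

**PPG.** The red (660 nm) and infrared (910 nm) channels are DC levels with
a sinusoidal pulsatile component at the heart rate. The IR modulation depth
(peak-to-trough AC over DC) defaults to 4%; the red depth is *solved from
the oximetry model itself*: given a target SpO2, the calibration table is
inverted to the ratio value R and `m_red = m_ir ** R`, which is the exact
inverse of the log-ratio formula below. Round-trip recovery is therefore
table-independent: swap in any monotone calibration and the generator still
encodes what the estimator decodes.

**Thermal.** 8x8 frames at a baseline of 22 C with i.i.d. Gaussian pixel
noise (sd 0.1 C, configurable; the sensor datasheet-level noise is not
modelled further). `warming` adds a 0.08 C/s ramp on a central 2x2 region —
the order of magnitude implied by a cabin reaching the 40 C critical level
in about eight minutes on a summer day. `flame` places two localized pixels
flickering at 0.6-1.0 x 180 C with large frame-to-frame transitions.

**Capacitive coupling channel.** Each insulating layer between the body and
the electrode plate (clothing, air gap, seat textile) is a series LC
impedance `Z_i = jwL_i + 1/(jwC_i)`; layers sum to `Z_tot`, which forms a
voltage divider against the amplifier input impedance:
`H(w) = Z_in / (Z_in + Z_tot)`. The divider is applied in the frequency
domain (real FFT), with `H(0) = 0` whenever a capacitive layer is present
(capacitors block DC). Vehicle electrical noise is added on top: 50 Hz mains
hum and Poisson-timed biphasic one-sample spikes (ignition / inductive
transients). No published component values exist for through-clothing
coupling in this setting, so the defaults are illustrative:
two layers of 100 pF and 220 pF (typical order for fabric-gap coupling),
`Z_in` = 100 Mohm, hum 0.1 and spikes 0.5 in the signal's own units
(sized against a millivolt-scale ECG), 0.5 spikes/s. The channel with no
layers and zero noise is the identity, and the linear part is exactly
linear, both of which are property-tested.

## Conditioning

The interference chain is: centred sliding mean (default 5 samples — the
"sliding filter" is interpreted as a centred moving average), Butterworth
band-pass (order 4; the ECG band of interest is 0.5-35 Hz), and a 50 Hz
IIR notch with Q = 30. All IIR filters run forward-backward
(`filtfilt`/`sosfiltfilt`), so conditioning is zero-phase: an in-band tone's
cross-correlation against its filtered version peaks at lag zero, and
R-peak positions are not shifted.

Wavelet machinery uses the dyadic Haar family. `dwt_coeffs` is the
orthonormal decomposition (periodized boundaries), so coefficients equal
brute-force inner products with explicit Haar basis vectors and energy is
preserved. Denoising uses the stationary (undecimated) transform at 3
levels: symmetric-reflection padding to a multiple of 2^levels, per-level
soft thresholding of details, inverse transform, un-pad. The default
threshold is the universal rule `sigma_hat * sqrt(2 ln N)` with `sigma_hat`
from the median absolute deviation of the finest details (a principled
default standing in for hand-tuned per-level values, which remain available
via the `fixed` rule). Zero thresholds give perfect reconstruction; on
lengths divisible by 2^levels the denoiser is circular-shift-equivariant.

## Welch spectral estimation and drowsiness

The Welch estimator is written out explicitly rather than delegated, because
it is the analytic core of the EEG stage (scipy's implementation is used
only as an independent cross-check in tests). Segments
`x_i[n] = x[n + iD]` of length M with hop D give `K = floor((N-M)/D) + 1`
segments; each is tapered (default Hann — the taper is a package choice)
and turned into a modified periodogram `|DFT(x_i w)|^2 / (M U)` with window
power normalisation `U = (1/M) sum w^2`; the estimate is the arithmetic mean
over segments. One-sided *density* scaling is used (divide by fs, double
interior bins) so the integral over [0, fs/2] estimates the variance; this
convention choice is exercised by a Parseval check and by an independent
direct-summation transcription of the defining sums that the estimator must
match to 1e-10 relative.

Defaults follow the analysis protocol of the EEG stage: 8-second segments
at 50% overlap, epochs of 8 s. Drowsiness scoring computes alpha (8-12 Hz)
and beta (14-25 Hz) band powers by trapezoidal integration of the PSD (band
edges interpolated, so a partition of [0, fs/2] sums exactly to the total),
forms the alpha/beta ratio, and flags an epoch drowsy when the ratio exceeds
`threshold_mult` (default 1.5) times a personal eyes-open baseline ratio,
with a 2-epoch persistence requirement in the monitoring pipeline. The
numeric threshold and persistence are package choices — the underlying
criterion is only qualitative (alpha up, beta down). A vanishing beta power
yields an `indeterminate` flag rather than a division error.

## Heart rate and oximetry

R-peak detection is a Pan-Tompkins-style derivative-square-integrate
detector: 5-15 Hz band-pass, derivative, squaring, 150 ms moving-window
integration, candidate peaks at a 250 ms refractory spacing, and an adaptive
threshold at half the running median of the last 8 accepted integrated peak
heights (seeded by the 90th percentile of all candidate heights, which sits
inside the QRS cluster even when low inter-beat bumps dominate the candidate
count). All thresholds are relative, so detection is invariant to positive
amplitude scaling. Rate bands default to normal 70-90 bpm, with 40-60 and
100-120 bpm as maximal-violation candidates; a rate in the ambiguous
100-120 overlap is labelled yellow with a red-candidate flag, because red
standing requires a second violated metric (an alert-engine rule). The
arrhythmia flag is an RR coefficient of variation above 0.15 — a simple
irregularity proxy, not a rhythm diagnosis.

Oximetry implements the log-ratio form of the ratio of ratios exactly as the
device formula states it:
`R = log(I_AC_R / I_DC_R) / log(I_AC_IR / I_DC_IR)`. Note this differs from
the more common `(AC_R/DC_R) / (AC_IR/DC_IR)` form; both logs are negative
(AC < DC), R is positive, and larger R means lower saturation. AC is the
mean beat-wise peak-to-trough amplitude, DC the windowed mean. Device
calibration tables are proprietary, so the package ships a documented
synthetic default (seven monotone knots spanning 70-100% SpO2) and accepts
user tables as CSV; estimates are median-smoothed over 3 windows before
alerting. Zero AC is reported as indeterminate, not as an error.

## Thermal classification

Per-frame statistics (max/mean/argmax, whole-frame and per named region
mask) and a per-pixel least-squares temperature slope feed a four-way
classifier with fixed precedence flame > overheat > warming > ambient:
flame on any upward frame-to-frame jump >= 15 C or any pixel at or above
60 C; overheat on any pixel of the latest frame at or above the 40 C
critical level; warming on any pixel slope >= 0.04 C/s *and* fitted total
rise >= 0.5 C over the gradient window. The rise requirement exists because
a slope threshold alone is not noise-robust: with pixel noise sd 0.1 C, the
maximum of 64 independent slope estimates over a short window routinely
exceeds 0.04 C/s. The jump/level numbers are documented defaults (the
underlying description of flame signatures is qualitative). Severity is
monotone under heating of the latest frame; heating an *earlier* frame can
legitimately reduce a temporal gradient, which is why the monotonicity
property is stated (and tested) for final-frame and uniform heating.

## Alert engine

Metric severities: heart rate red at <= 60 or > 100 bpm, yellow otherwise
outside the normal band; SpO2 red below 90%, yellow 90-94%, normal at or
above 95%; the drowsiness and arrhythmia flags each count as one
maximal-violation metric; thermal overheat/flame is red, warming yellow.
Phase logic per snapshot history: impact anywhere forces phase 5; else
phase 4 when at least two metrics have held red for the persistence window
(default 10 s — the "declared period of time" is not quantified anywhere,
so it is a configurable package default); else phase 3 when any metric has
held beyond normal for the persistence window; else phase 2 (phase 1 while
a training-mode config is active). De-escalation hysteresis is implemented
as a pure function of history — the decision is the maximum banded phase
over the trailing persistence window — so streaming evaluation trivially
equals batch replay, and the whole engine is deterministic and reproducible
from the snapshot log.

`calibrate` learns a personal normal band (mean +/- 3 sd over a training
stream of at least 60 s) clipped to stay strictly inside the printed
yellow/red boundaries; with an insufficient baseline it falls back to the
defaults with a warning. The pre-impact ring buffer keeps snapshots within
30 s of the newest, boundary inclusive (so 60 s of 1 Hz snapshots retain
31). The e-Call payload (schema-versioned pydantic model) carries vehicle
id, occupant count (echoed from configuration — presence sensing is out of
scope), the ring-buffer snapshots in time order, position, and dynamics
placeholders that are null when unavailable but never omitted.

## Cognitive-state classifier

The published description of the cognitive-state network (RBF features, a
recurrent element, an MLP head) is ambiguous, so the package implements the
smallest fully specifiable variant: per-epoch spatial transform
(standardise to unit variance, then alpha power, beta power, log alpha/beta
ratio, spectral entropy of the normalised 1-45 Hz spectrum — invariant to
per-epoch gain), RBF activations `exp(-gamma ||x - c||^2)` around K = 12
prototypes from seeded k-means in standardised feature space (gamma = 1),
and a one-hidden-layer MLP (16 units, lbfgs) on the activations. An
optional exponential smoothing of per-epoch scores across consecutive
epochs honours the sequence framing without introducing untestable gates.
All randomness sits behind one seed; refits are bit-identical, and training
order is irrelevant.

The 4-class benchmark (relaxation / stress / emotion / distraction, 30
epochs per class, 8 s at 250 Hz, amplitudes jittered +/-15%) is a
self-defined bar: held-out accuracy must reach 90%. Because class
signatures are separated in exactly the features the transform measures,
this validates the pipeline's plumbing and determinism — it says nothing
about accuracy on real EEG, and no published field figure is reproduced.

## Problem sizes and reproducibility

Validation runs at desk scale as a package choice: 60 s ECG records for
rate recovery, 10 s PPG windows, 100-epoch drowsiness sweeps at 250 Hz,
60-frame thermal sequences, 120-epoch classifier benchmarks. Every stochastic
path takes an explicit integer seed; identical seeds give bit-identical
traces, event logs and fitted models. `scripts/acceptance.py` recomputes the
worked-example quantities (alert phases for three canonical streams, the
alpha-component amplitude bound) from scratch on each run.

## Known limitations

- Tone-based EEG and sinusoidal PPG pulses are far cleaner than field
  signals; motion artifacts, electrode repositioning and 1/f background are
  unmodelled.
- The ECG classes are morphology presets, not patient models; no
  blood-pressure estimation is attempted.
- The calibration table is synthetic; absolute SpO2 accuracy on a real
  sensor requires a device-specific table.
- The capacitive-channel layer values are illustrative; only the structure
  of the model (series LC divider + hum + spikes) is meaningful.
- Occupant counting, vehicle dynamics and the transport layer of e-Call are
  configuration pass-throughs, not sensed quantities.
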