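# drivevitals

Non-contact driver condition monitoring as a tested Python library and CLI.

Semi-autonomous vehicles need to know whether the person in the driver's
seat could take control: drowsiness, arrhythmia, low blood oxygen or a cabin
fire all disqualify them, and after a collision the pre-impact vitals are
exactly what an e-Call / telemedicine rescue chain wants. `drivevitals`
implements the full signal chain of such a system for researchers and
engineers prototyping in-cabin monitoring — from the physics of a
through-clothing capacitive electrode down to the emergency payload —
against synthetic signals with known ground truth, since real in-cabin
recordings of this kind are not publicly available.

The stack:

- **Synthetic signals** (`drivevitals.synth`) — P-QRS-T ECG morphology in
  three blood-pressure classes, state-dependent alpha/beta EEG mixtures,
  dual-wavelength (660/910 nm) PPG with encoded SpO2, 8x8 thermal frame
  sequences, and a capacitive-coupling channel: each clothing layer is a
  series impedance Z_i = jwL_i + 1/(jwC_i), summed into a voltage divider
  against the amplifier input impedance, plus 50 Hz hum and ignition spikes.
- **Conditioning** (`drivevitals.conditioning`) — zero-phase sliding-mean /
  Butterworth band-pass (0.5-35 Hz) / 50 Hz notch chain, orthonormal Haar
  DWT, and 3-level stationary-wavelet soft-threshold denoising.
- **Spectral analysis** (`drivevitals.spectral`) — an explicit Welch PSD
  estimator: segments x_i[n] = x[n+iD], modified periodograms
  |DFT(x_i w)|^2/(M U) with U = (1/M) Σ w^2, averaged; alpha (8-12 Hz) /
  beta (14-25 Hz) band powers on 8-s epochs and an alpha/beta drowsiness
  ratio against a personal baseline.
- **Vitals** (`drivevitals.ecg`, `drivevitals.oximetry`) — Pan-Tompkins
  style R-peak detection with RR statistics, and SpO2 via the ratio of
  ratios R = log(I_AC_R/I_DC_R)/log(I_AC_IR/I_DC_IR) mapped through a
  monotone calibration table.
- **Thermal** (`drivevitals.thermal`) — 64-point frame statistics, per-pixel
  temperature gradients, and ambient/warming/overheat/flame classification
  (critical level 40 °C).
- **Alerting** (`drivevitals.alerts`) — the five-phase state machine
  (training, green, yellow, red, collision) with per-metric bands,
  persistence, ring buffer and e-Call payload.
- **Classifier** (`drivevitals.classifier`) — a cognitive-state classifier:
  gain-invariant band features, RBF prototype activations from seeded
  k-means, MLP head.
- **Interface** (`drivevitals.pipeline`, `drivevitals.cli`) — CSV/JSON/JSONL
  dialects, schema-validated configuration, drive scenarios and the
  end-to-end `monitor` flow.

## Worked example

Simulate a quiet 20-second drive, then analyse each stream:

```
$ drivevitals simulate --scenario quiet_drive --duration 20 --seed 1 --out scen
wrote scenario 'quiet_drive' (20 s, seed 1) to scen

$ drivevitals ecg-hr scen/ecg.csv
25 beats, hr 75.0 bpm, RR CV 0.015, band normal

$ drivevitals eeg-psd scen/eeg_epoch_000.csv --out psd.csv
alpha[8-12 Hz] 51.61 beta[14-25 Hz] 199.73 ratio 0.258

$ drivevitals spo2 scen/ppg_red.csv scen/ppg_ir.csv
SpO2 98.0% (R = 0.967)
```

The scenario encodes hr 75 bpm, SpO2 98% and an alert (eyes-open) EEG; the
detector recovers the rate exactly, the alpha/beta ratio is well below 1
(beta dominates while alert), and the oximetry pipeline decodes the
saturation the generator encoded. A collision scenario exercises the whole
state machine:

```
$ drivevitals monitor --scenario collision --duration 60
t=  10.0s phase 2 (green)
...
t=  60.0s phase 5 (collision) triggers ['impact']
e-Call payload with 4 pre-impact snapshots
```

Library use mirrors the CLI:

```python
from drivevitals import (EcgProfile, gen_ecg, detect_r_peaks,
                         apply_capacitive_channel)
from drivevitals.synth import DEFAULT_CHANNEL
from drivevitals.conditioning import condition_ecg

ecg = gen_ecg(EcgProfile.for_class("normal", hr_bpm=75), 60.0, fs=500, seed=1)
noisy = apply_capacitive_channel(ecg, DEFAULT_CHANNEL)
print(detect_r_peaks(condition_ecg(noisy)).hr_bpm)   # 75.0
```

See `docs/methods.md` for the models, defaults and their rationale.

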