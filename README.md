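# emgdi

Automatic detection of inspiratory activity cycles — and their onset and
offset instants — in long, ECG-contaminated surface diaphragm EMG (EMGdi)
recordings.

Surface EMGdi reflects neural inspiratory drive and is the signal of choice
for quantifying patient–ventilator asynchrony (ineffective efforts, delayed
cycling) during non-invasive ventilation, but it is buried in cardiac
artifact and its quality drifts over a night. This package is for
respiratory physiologists and biomedical engineers who need reproducible,
fully automatic cycle timing from such recordings, plus the simulation
tooling to calibrate and audit the detector.

## Method

- **ECG suppression** (four interchangeable options): adaptive-threshold
  db4 wavelet denoising, 45 Hz high-pass + QRS gating, LMS adaptive
  cancellation against a self-synthesized cardiac reference, and adaptive +
  gating. R-peaks come from a Pan–Tompkins detector on the 5–40 Hz band.
- **Envelopes**: e1 is a 250 ms sliding RMS or fixed sample entropy
  (fSE: m = 1, tolerance r = 0.4·SD of the whole record — fixed, which
  makes the envelope sensitive to random EMG amplitude but nearly blind to
  the repetitive, deterministic ECG); e2 = 300 ms moving average of e1;
  e3 = 10^ê2 with ê2 the Min-Max-normalized e2.
- **Cycle detection**: maximal runs where the 1 s moving average of the
  envelope exceeds the 3 s moving average, annotated at the run midpoint,
  filtered by duration (≥ 200 ms), amplitude margin (inside mean ≥ 1.1 ×
  flank mean) and a Shannon-entropy plausibility check. Onsets/offsets are
  localized against adaptive thresholds: the KDE mode of the envelope
  between neighboring cycles.
- **Timing-bias correction**: the detector's mean timing error ME
  (detected − true; negative = early) is characterized on simulated
  records across the inspiratory-to-basal SNR, I2BSNR = 20·log₁₀(RMS_insp
  / RMS_basal), and fitted with a double exponential

      c(I2BSNR) = a·e^(b·I2BSNR) + c·e^(d·I2BSNR),

  separately for onsets and offsets. Detected marks are corrected per
  30 s epoch by subtracting c at the epoch's estimated I2BSNR.
- **Evaluation**: two-scorer reference construction (overlap pairing,
  reliable markers at < 150 ms inter-scorer difference, mean-of-scorers
  reference), TP/FP/FN with sensitivity/precision/F1, and MD/SD/RMSE
  timing metrics.

## Worked example

```python
import numpy as np
from emgdi import (SimulationSpec, simulate_emgdi, bandpass, compute_envelope,
                   detect_cycles, compute_i2bsnr, run_bias_simulation,
                   fit_correction, apply_correction)

# 50 synthetic cycles at inspiratory/basal RMS ratio 2 (~6 dB I2BSNR)
record, truth = simulate_emgdi(SimulationSpec(n_cycles=50, rms_ratio=2.0,
                                              seed=42))
record = bandpass(record)

env = compute_envelope(record, method="fse", stage="e3")
cycles, _ = detect_cycles(env)
print(f"detected {len(cycles)} of {truth.n_cycles} cycles")

errs = [c.onset - on for c, (on, off) in zip(cycles, truth.intervals())]
print(f"uncorrected onset bias: {1e3 * np.mean(errs):+.0f} ms")

# calibrate the correction on an independent simulation sweep
grid = np.linspace(1.58, 20.0, 9)
table = run_bias_simulation(grid, n_cycles=100, seed=7, method="fse_e3")
model = fit_correction(table)
print(model.summary())

corrected = apply_correction(cycles, compute_i2bsnr(record, cycles), model)
errs_c = [c.onset_corrected - on
          for c, (on, off) in zip(corrected, truth.intervals())]
print(f"corrected onset bias:   {1e3 * np.mean(errs_c):+.0f} ms")
```

Output:

```
detected 50 of 50 cycles
uncorrected onset bias: -141 ms
Timing-bias correction model (fse_e3)
  valid I2BSNR range: 1.58 - 20.00 dB
  onset : c(s) = +0.1696 exp(-0.5278 s) -0.1678 exp(-0.0351 s)   [fit RMSE 3.1 ms]
  offset: c(s) = +0.1490 exp(-0.0300 s) -1113.9115 exp(-6.3077 s)   [fit RMSE 4.0 ms]
corrected onset bias:   -12 ms
```

All 50 simulated efforts are found; the raw detector marks onsets ~141 ms
early (envelope smearing), and subtracting the fitted, SNR-dependent bias
brings that to −12 ms — inside typical clinical timing tolerances.

The same workflow is available from the shell:

```sh
emgdi simulate --cycles 50 --ratio 2 --seed 42 -o sim
emgdi fit-correction --levels 9 --cycles 100 --seed 7 --method fse_e3 -o model.json
emgdi detect -i sim.csv --ecg none --env fse --stage e3 --correction model.json -o cycles.csv
emgdi evaluate --detected cycles.csv --scorer-a a.csv --scorer-b b.csv -o report.json
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch, the detector's
simulation-calibrated timing-error figures: it simulates the 9-level
I2BSNR sweep (RMS ratios 1.2–10, 200 cycles per level), runs the RMS e2
and e3 envelope detectors through the full chain, and reports the grand
mean |ME| across the grid (e2) and the asymptotic |ME| at 20 dB (e3):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Limitations

Validated on synthetic Gaussian-noise EMGdi with known truth; clinical
recordings add artifacts and variability this world does not model (see
`docs/methods.md`). EDF/WFDB input requires readers not bundled here —
convert to CSV (`time_s,amplitude`).
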