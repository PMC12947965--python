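# Methods

`emgdi` detects inspiratory activity cycles — and their onset and offset
instants — in long, ECG-contaminated surface diaphragm EMG (EMGdi)
recordings, such as overnight recordings from COPD patients on non-invasive
ventilation. This note documents the processing model, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not establish.

## Processing model

1. **Conditioning.** Zero-phase 4th-order Butterworth band-pass, 5–200 Hz
   (clipped to 0.95 × Nyquist with a warning when the rate requires it).
   Optional mains notching: per harmonic, a zero-phase IIR notch whose Q is
   multiplied/divided by 1.25 (start Q = 35, ≤ 20 iterations) until the
   residual power in a ±1 Hz band at the harmonic matches the mean power of
   the two ±1 Hz sidebands centered ±3 Hz away, within 10 %.
2. **QRS detection.** Pan-Tompkins on the 5–40 Hz band: derivative,
   squaring, 150 ms moving-window integration, adaptive dual thresholds
   (0.125/0.875 learning), 200 ms refractory, 1.66 × RR search-back; peaks
   refined to the local |5–40 Hz| extremum within ±40 ms. Trains whose rate
   falls outside 30–200 bpm, or with a weak signal-to-noise threshold
   separation, are flagged `low_confidence`; downstream stages tolerate
   them (the pipeline then skips exclusion masking).
3. **Cardiac-artifact suppression** (four options): db4 wavelet
   thresholding to level 4 (approximation below fs/32 discarded; detail
   coefficients clipped at 5 × the robust scale of out-of-window
   coefficients, inside R-peak-centered windows growing from 200 ms at
   level 1 to 300 ms at level 4); gating (45 Hz 2nd-order zero-phase
   high-pass, then each 130 ms R-centered window replaced by the line
   joining the flanking 65 ms RMS values); LMS adaptive cancellation
   (beat template averaged from the [−200, +400] ms segments after
   discarding the top 25 % by energy, tiled at the R-peaks as reference,
   0.4 s of weights, step searched until cancellation energy matches
   reference energy within 5 %); and adaptive + gating without the
   high-pass.
4. **Envelopes.** e1 = 250 ms centered sliding RMS, or fixed sample
   entropy (m = 1, tolerance r = 0.4 × SD of the whole conditioned record,
   fixed — not per window). e2 = 300 ms moving average of e1. e3 = 10^ê2
   with ê2 the per-record Min-Max normalization of e2, so e3 ∈ [1, 10].
   The entropy envelope is refused after gating or wavelet denoising:
   those stages overwrite/truncate the samples around each QRS, carving
   artificial low-complexity notches into the entropy trace.
5. **Cycle detection.** Events are maximal runs where the 1 s moving
   average of the envelope exceeds the 3 s moving average, annotated at
   the run's temporal midpoint. Runs shorter than 200 ms are rejected;
   runs whose inside-mean does not exceed the pooled mean of two flanking
   windows (20 % of the run duration each) by 10 % are rejected.
6. **Onset/offset localization.** Thresholds are the Gaussian-KDE mode
   (Silverman bandwidth, argmax on a 512-point grid) of the envelope
   between the current marker and the previous/next accepted marker (or
   record edge). From the marker, the scan walks outward while the
   envelope stays above the threshold; the onset/offset is the last sample
   above it. Localized cycles shorter than 200 ms, and cycles whose
   in-burst Shannon entropy (32 equal-width bins over the pooled range of
   the three phases, natural log, 0·log 0 = 0) is below either adjacent
   between-cycle phase, are rejected.
7. **Signal quality.** I2BSNR per 30 s epoch: 20·log10 of the RMS over
   in-cycle samples divided by the RMS over out-of-cycle samples, both
   restricted to samples outside the cardiac exclusion windows
   ([−135, +365] ms around each R-peak, inclusive integer sample bounds).
   Epochs with under 250 ms of either class are missing and carried
   forward from the last valid epoch (leading gaps back-filled).
8. **Bias correction.** On simulations the detector's mean timing error
   (ME, detected − true) per I2BSNR level is tabulated and fitted with
   c(s) = a·e^{bs} + c·e^{ds} by multi-start nonlinear least squares
   (sign patterns of (a, c) × decay inits {−0.5, −0.05}; single-
   exponential fallback). Applied per epoch: corrected = mark − c(I2BSNR),
   with the SNR clamped to the fitted range so the exponentials never
   extrapolate. Only the mean error is corrected; the dispersion (SD) is
   reported untouched. The double-exponential family fits RMS-e3 onset
   curves poorly; fitting them emits a warning.

## Synthetic-data generator

The generator emulates the validation world: zero-mean Gaussian white
noise whose SD is modulated once per cycle (default period 2 s) by the
parabolic gain e(t) = 1 − 4(t − 1)² on t ∈ [0.5, 1.5]. The modulation is
g(t) = 1 + α·e(t) with α calibrated analytically (using ∫e = 2/3 and
∫e² = 8/15 over the support) so that the realized inspiratory-segment RMS
over basal RMS equals the requested `rms_ratio` exactly in expectation —
this is what makes ratio 1.2 ↔ 1.58 dB and ratio 10 ↔ 20 dB, and it implies
a peak gain above `rms_ratio`. Optional extras for exercising the artifact
stages (the validation protocol itself uses pure noise): an additive
sum-of-Gaussians P-QRS-T train with 2 % RR jitter, R amplitude expressed in
multiples of the record's robust basal RMS (1.4826 × MAD), and a 50 Hz
sinusoid with RMS a stated fraction of the basal SD.

What the generator does **not** model: motor-unit structure and EMG
spectral shape, baseline wander, motion/electrode artifacts, breath-to-
breath variability of period and depth, and real QRS morphology variation.
A green test on this world therefore establishes algorithmic correctness
and the stated orderings (entropy-envelope robustness to repetitive
artifacts, early-onset/late-offset bias and its SNR dependence), not
clinical-grade performance on patient data.

## Numerical choices and degenerate inputs

- All moving windows are centered; even sample counts take the extra
  sample on the left; edges shrink to the available samples. Envelope
  sample k is aligned with signal sample k at every stage.
- Cardiac exclusion windows use integer sample offsets (round-half-even)
  with inclusive endpoints — 251 samples at 500 Hz — and merge by union.
- Fixed-sample-entropy windows with no length-2 match take the ceiling
  ln(B(B−1)); windows with no match at all copy the nearest defined
  value; an everywhere-undefined envelope degrades to zeros with a
  warning. Templates are drawn from all window samples but the last, so
  A/B is a proper conditional probability and a constant window gives
  exactly 0.
- A constant e2 envelope yields an all-ones e3 with a warning; a constant
  KDE segment returns its value + ε as threshold, which rejects the
  dependent cycle as zero-duration.
- Timing-error SDs and the evaluation SD use the population convention
  (ddof = 0) so RMSE² = MD² + SD² holds as an identity.
- The LMS canceller and the sliding entropy counts are compiled with
  numba; brute-force Python oracles in the test suite verify both.

## Known limitations

- At the lowest simulated quality (1.58 dB) the RMS-e1 detector resolves
  only ~65 % of cycles and the surviving subset is biased: noise dips
  terminate the threshold scan early, so the early-onset/late-offset sign
  structure is not resolved at that single level (it holds at every level
  with ≥ 90 % detection). The e2/e3 stages do not show this.
- The KDE threshold grid (512 points over the segment's value range)
  loses resolution when a segment's dynamic range is many orders of
  magnitude (e.g. an isolated spike on a nearly constant baseline): the
  mode can then fall below the baseline and the onset/offset scan runs
  long. Bounded envelopes (e3 ∈ [1, 10]) avoid this by construction.
- EDF/WFDB readers are not bundled (no reader library available);
  records are exchanged as CSV.
- The Q-factor notch search matches band power on the analyzed record; on
  very short records (< ~8 s) the Welch estimate is too coarse for the
  10 % criterion and the filter keeps its last Q with a warning.
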