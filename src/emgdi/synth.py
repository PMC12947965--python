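"""Synthetic EMGdi generator with known ground-truth cycle timing.

The stochastic diaphragm EMG is modelled as zero-mean Gaussian white noise
whose standard deviation is amplitude-modulated once per respiratory cycle
by the parabolic inspiratory envelope

    e(t) = 1 - 4 (t - 1)^2   for 0.5 <= t <= 1.5,   0 otherwise,

with ``t`` in seconds inside one cycle period (default 2 s, i.e. inspiration
from 0.5 s to 1.5 s and basal expiration elsewhere).  The modulation gain is
calibrated so that the realized RMS over the whole inspiratory support
divided by the basal RMS equals the requested ``rms_ratio``, which makes the
inspiratory-to-basal SNR exactly ``20 log10(rms_ratio)`` dB in expectation
(ratio 1.2 -> 1.58 dB, ratio 10 -> 20 dB).

Optionally a deterministic sum-of-Gaussians P-QRS-T cardiac artifact and a
50 Hz mains sinusoid can be superimposed so the ECG-suppression and notch
stages can be exercised against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .preprocess import Record, RPeakTrain

__all__ = [
    "EcgSpec",
    "SimulationSpec",
    "GroundTruth",
    "inspiratory_envelope",
    "simulate_emgdi",
    "inject_ecg",
]

#: inspiratory support inside one cycle period, seconds
INSP_START = 0.5
INSP_END = 1.5

# Analytic moments of e(t) over its 1 s support: int e = 2/3, int e^2 = 8/15.
_E_MEAN = 2.0 / 3.0
_E_SQ_MEAN = 8.0 / 15.0


@dataclass(frozen=True)
class EcgSpec:
    """Synthetic cardiac artifact description.

    ``qrs_amplitude`` scales the R wave as a multiple of the basal EMG RMS
    (estimated robustly from the host record); the P/Q/S/T waves keep fixed
    proportions of the R amplitude.
    """

    heart_rate: float = 70.0
    qrs_amplitude: float = 8.0
    template: str = "pqrst"

    def __post_init__(self) -> None:
        if not 30.0 <= self.heart_rate <= 200.0:
            raise ValueError("heart_rate must lie in [30, 200] bpm")
        if self.qrs_amplitude < 0:
            raise ValueError("qrs_amplitude must be >= 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic EMGdi record."""

    n_cycles: int
    rms_ratio: float
    seed: int
    sampling_rate: float = 500.0
    cycle_period: float = 2.0
    basal_sd: float = 1.0
    ecg: Optional[EcgSpec] = None
    mains_amplitude: float = 0.0
    mains_freq: float = 50.0

    def __post_init__(self) -> None:
        if self.rms_ratio < 1:
            raise ValueError("rms_ratio must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.cycle_period < 2.0:
            raise ValueError(
                "cycle_period must be >= 2 s so the inspiratory support fits")
        if self.mains_amplitude < 0:
            raise ValueError("mains_amplitude must be >= 0")


@dataclass
class GroundTruth:
    """True cycle timing of a simulated record (seconds)."""

    onsets: np.ndarray
    offsets: np.ndarray
    cycle_markers: np.ndarray
    r_peaks: Optional[RPeakTrain] = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.cycle_markers = np.asarray(self.cycle_markers, dtype=float)
        for arr in (self.onsets, self.offsets, self.cycle_markers):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError("ground-truth times must be strictly increasing")
        if not np.allclose(self.offsets - self.onsets, INSP_END - INSP_START):
            raise ValueError("each cycle's inspiratory support must last exactly 1 s")

    @property
    def n_cycles(self) -> int:
        return self.onsets.size

    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.onsets.tolist(), self.offsets.tolist()))


def inspiratory_envelope(t):
    """Parabolic within-cycle amplitude gain ``e(t)``.

    Accepts a scalar or array of nonnegative times (seconds within one cycle
    period) and returns ``1 - 4 (t - 1)^2`` on [0.5, 1.5] and 0 elsewhere.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be >= 0")
    e = np.where((arr >= INSP_START) & (arr <= INSP_END),
                 1.0 - 4.0 * (arr - 1.0) ** 2, 0.0)
    return float(e) if e.ndim == 0 else e


def _gain_alpha(rms_ratio: float) -> float:
    """Envelope gain coefficient alpha such that the expected mean square of
    ``1 + alpha e(t)`` over the inspiratory support equals ``rms_ratio**2``.

    Solves (8/15) a^2 + (4/3) a + (1 - r^2) = 0 for the positive root.
    """
    r2 = rms_ratio * rms_ratio
    if r2 <= 1.0:
        return 0.0
    disc = (2 * _E_MEAN) ** 2 + 4.0 * _E_SQ_MEAN * (r2 - 1.0)
    return (-2 * _E_MEAN + np.sqrt(disc)) / (2.0 * _E_SQ_MEAN)


def simulate_emgdi(spec: SimulationSpec) -> tuple[Record, GroundTruth]:
    """Generate one synthetic EMGdi record and its ground truth.

    The same ``spec`` (including the seed) always produces a bit-identical
    sample stream.  When ``spec.ecg`` is set, the cardiac artifact's true
    R-peak train is attached to the returned :class:`GroundTruth`.
    """
    fs = spec.sampling_rate
    period = spec.cycle_period
    n = int(round(spec.n_cycles * period * fs))
    rng = np.random.default_rng(spec.seed)

    t = np.arange(n) / fs
    gain = 1.0 + _gain_alpha(spec.rms_ratio) * inspiratory_envelope(t % period)
    x = rng.standard_normal(n) * spec.basal_sd * gain

    if spec.mains_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        # sinusoid amplitude chosen so its RMS is the stated fraction of basal RMS
        amp = np.sqrt(2.0) * spec.mains_amplitude * spec.basal_sd
        x = x + amp * np.sin(2 * np.pi * spec.mains_freq * t + phase)

    rec = Record(x, fs, label="synthetic EMGdi", units="au")

    k = np.arange(spec.n_cycles)
    truth = GroundTruth(onsets=k * period + INSP_START,
                        offsets=k * period + INSP_END,
                        cycle_markers=k * period + 1.0)

    if spec.ecg is not None:
        rec, rpeaks = inject_ecg(rec, spec.ecg, seed=spec.seed + 1)
        truth.r_peaks = rpeaks
    return rec, truth


# sum-of-Gaussians P-QRS-T template: (center s, width s, relative amplitude)
_PQRST = (
    (-0.200, 0.025, 0.12),   # P
    (-0.028, 0.010, -0.18),  # Q
    (0.000, 0.012, 1.00),    # R
    (0.030, 0.010, -0.22),   # S
    (0.260, 0.055, 0.28),    # T
)


def _beat_template(fs: float) -> tuple[np.ndarray, int]:
    """One P-QRS-T beat sampled at ``fs``; returns (waveform, R index)."""
    half = int(round(0.45 * fs))
    tt = np.arange(-half, half + 1) / fs
    w = np.zeros_like(tt)
    for c, s, a in _PQRST:
        w += a * np.exp(-0.5 * ((tt - c) / s) ** 2)
    w /= np.max(w)          # R wave peaks at exactly 1
    return w, half


def inject_ecg(record: Record, ecg: EcgSpec,
               seed: int) -> tuple[Record, RPeakTrain]:
    """Additively superimpose a periodic P-QRS-T artifact on a record.

    The R amplitude is ``ecg.qrs_amplitude`` times the record's robust basal
    RMS (1.4826 x median absolute deviation, insensitive to inspiratory
    bursts).  Beat-to-beat intervals carry 2 % Gaussian jitter drawn from
    ``seed``.  The artifact is purely additive: subtracting the injected
    trace restores the input exactly.  Returns the contaminated record and
    the true R-peak train.
    """
    if record.n_samples == 0:
        raise ValueError("record must be non-empty")
    fs = record.sampling_rate
    rng = np.random.default_rng(seed)
    rr = 60.0 / ecg.heart_rate

    basal_rms = 1.4826 * float(np.median(np.abs(record.samples)))
    if basal_rms == 0:
        basal_rms = 1.0
    scale = ecg.qrs_amplitude * basal_rms

    w, r_off = _beat_template(fs)
    trace = np.zeros(record.n_samples)
    peaks = []
    t_peak = 0.5 * rr
    while t_peak < record.duration:
        p = int(round(t_peak * fs))
        if p < record.n_samples:
            a = p - r_off
            b = a + w.size
            wa, wb = max(0, -a), w.size - max(0, b - record.n_samples)
            trace[max(0, a):min(b, record.n_samples)] += w[wa:wb]
            peaks.append(p)
        t_peak += rr * max(0.5, 1.0 + 0.02 * rng.standard_normal())
    out = record.replace(record.samples + scale * trace)
    return out, RPeakTrain(np.asarray(peaks, dtype=int), fs,
                           low_confidence=ecg.qrs_amplitude == 0)
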