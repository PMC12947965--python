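"""Conditioning of raw surface diaphragm EMG (EMGdi) records.

This module owns the basic containers (:class:`Record`, :class:`RPeakTrain`,
:class:`SampleMask`, :class:`I2BSNRSeries`) and the conditioning stages that
every downstream analysis relies on:

* zero-phase Butterworth band-pass filtering (5-200 Hz by default, matching
  the analogue acquisition band of surface EMGdi hardware),
* adaptive mains-interference notching whose Q factor is tuned until the
  residual line power matches the power in adjacent sidebands,
* QRS detection with a Pan-Tompkins style detector run on the 5-40 Hz band,
* cardiac exclusion masks (135 ms before to 365 ms after each R-peak),
* the inspiratory-to-basal signal-to-noise ratio (I2BSNR) per 30 s epoch,
  the signal-quality index that drives the timing-bias correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._windows import moving_mean, window_samples

__all__ = [
    "Record",
    "RPeakTrain",
    "SampleMask",
    "I2BSNRSeries",
    "bandpass",
    "notch_mains",
    "detect_r_peaks",
    "ecg_exclusion_mask",
    "compute_i2bsnr",
    "ratio_to_db",
]


@dataclass
class Record:
    """A sampled single-channel signal.

    Parameters
    ----------
    samples : array-like of float
        Signal amplitudes.  Must be finite.
    sampling_rate : float
        Sampling frequency in Hz, > 0.
    label, units : str
        Free-text channel metadata.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = "EMGdi"
    units: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Record.samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Record.samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def replace(self, samples: np.ndarray, label: str | None = None) -> "Record":
        return Record(samples, self.sampling_rate,
                      label if label is not None else self.label, self.units)


@dataclass
class RPeakTrain:
    """Detected (or known) cardiac R-peak positions, in samples.

    ``low_confidence`` marks trains recovered from signals where no clear
    cardiac activity was present; downstream stages tolerate these but the
    flag is propagated so results can be audited.
    """

    indices: np.ndarray
    sampling_rate: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1:
            d = np.diff(self.indices)
            if np.any(d <= 0):
                raise ValueError("R-peak indices must be strictly increasing")
            if np.any(d < 0.2 * self.sampling_rate):
                raise ValueError("R-peak train violates the 200 ms refractory period")

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.sampling_rate

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class SampleMask:
    """Boolean keep-mask over a record (False = excluded sample)."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_excluded(self) -> int:
        return int(np.sum(~self.keep))


@dataclass
class I2BSNRSeries:
    """Per-epoch inspiratory-to-basal SNR in dB (NaN = undefined epoch)."""

    epoch_starts: np.ndarray
    epoch_length: float
    values_db: np.ndarray

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.values_db = np.asarray(self.values_db, dtype=float)
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        if self.epoch_starts.shape != self.values_db.shape:
            raise ValueError("epoch_starts and values_db must align")

    def filled(self) -> np.ndarray:
        """Values with missing epochs carried forward from the last valid one
        (leading gaps are back-filled from the first valid epoch)."""
        v = self.values_db.copy()
        valid = np.isfinite(v)
        if not valid.any():
            return v
        idx = np.where(valid, np.arange(v.size), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(valid)
        idx[idx < 0] = first
        return v[idx]

    def value_at(self, t: float) -> float:
        """Carried-forward I2BSNR of the epoch containing time ``t``."""
        filled = self.filled()
        if filled.size == 0:
            return float("nan")
        k = int(np.clip(np.floor(t / self.epoch_length), 0, filled.size - 1))
        return float(filled[k])


def ratio_to_db(ratio: float) -> float:
    """Convert an RMS amplitude ratio to decibels, ``20 log10(ratio)``."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("ratio must be > 0")
    out = 20.0 * np.log10(ratio)
    return float(out) if out.ndim == 0 else out


def db_to_ratio(db: float) -> float:
    """Inverse of :func:`ratio_to_db`."""
    return float(10.0 ** (np.asarray(db, dtype=float) / 20.0))


def _bandpass_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(record: Record, low: float = 5.0, high: float = 200.0,
             order: int = 4) -> Record:
    """Zero-phase Butterworth band-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and the
    phase is exactly zero.  If ``high`` reaches the Nyquist frequency it is
    clipped to 0.95 x Nyquist with a warning.
    """
    fs = record.sampling_rate
    nyq = fs / 2.0
    if high >= nyq:
        clipped = 0.95 * nyq
        warnings.warn(
            f"band-pass upper edge {high} Hz >= Nyquist {nyq} Hz; "
            f"clipping to {clipped:.1f} Hz")
        high = clipped
    if not 0 < low < high:
        raise ValueError("need 0 < low < high < Nyquist")
    sos = _bandpass_sos(low, high, order, fs)
    # sosfiltfilt pads with ~3x the filter's impulse-response settling length
    padlen = 3 * (2 * sos.shape[0] + 1)
    if record.n_samples <= padlen:
        raise ValueError(
            f"record too short for zero-phase filtering "
            f"({record.n_samples} samples <= warm-up {padlen})")
    y = sps.sosfiltfilt(sos, record.samples)
    return record.replace(y)


def _band_power(psd_f: np.ndarray, psd: np.ndarray, center: float,
                half_width: float = 1.0) -> float:
    sel = np.abs(psd_f - center) <= half_width
    if not sel.any():
        return float("nan")
    return float(np.mean(psd[sel]))


def notch_mains(record: Record, base_freq: float = 50.0,
                n_harmonics: int = 1, q_start: float = 35.0,
                q_step: float = 1.25, max_iter: int = 20,
                tol: float = 0.10) -> Record:
    """Adaptive zero-phase IIR notch at the mains frequency and harmonics.

    For each harmonic the notch Q factor is widened or narrowed iteratively
    until the residual power in a +/-1 Hz band at the harmonic is within
    ``tol`` (10 %) of the mean power in two adjacent +/-1 Hz sidebands
    centered 3 Hz below and above.  If the criterion is not met after
    ``max_iter`` iterations the last Q is kept and a warning is issued.
    """
    fs = record.sampling_rate
    if base_freq * n_harmonics >= fs / 2:
        raise ValueError("harmonic frequency reaches Nyquist")
    y = record.samples.astype(float)
    nperseg = min(y.size, int(4 * fs))
    for h in range(1, n_harmonics + 1):
        f0 = base_freq * h
        q = q_start
        best = y
        converged = False
        for _ in range(max_iter):
            b, a = sps.iirnotch(f0, q, fs=fs)
            cand = sps.filtfilt(b, a, y)
            f, psd = sps.welch(cand, fs=fs, nperseg=nperseg)
            p0 = _band_power(f, psd, f0)
            psb = 0.5 * (_band_power(f, psd, f0 - 3.0)
                         + _band_power(f, psd, f0 + 3.0))
            best = cand
            if psb > 0 and abs(p0 / psb - 1.0) <= tol:
                converged = True
                break
            if p0 > psb:
                q /= q_step      # widen the notch
            else:
                q *= q_step      # narrow it
        if not converged:
            warnings.warn(
                f"notch at {f0:.0f} Hz did not meet the sideband criterion "
                f"after {max_iter} iterations; keeping last Q={q:.1f}")
        y = best
    return record.replace(y)


def detect_r_peaks(record: Record) -> RPeakTrain:
    """Pan-Tompkins style QRS detection on the 5-40 Hz band.

    Stages: zero-phase 5-40 Hz band-pass, derivative, squaring, 150 ms
    moving-window integration, adaptive dual thresholds with a 200 ms
    refractory period and 1.66 x RR search-back.  Detected positions are
    refined to the local extremum of the 5-40 Hz signal within +/-40 ms.
    """
    fs = record.sampling_rate
    if record.duration < 5.0:
        raise ValueError("QRS detection needs at least 5 s of signal")
    bp = bandpass(record, 5.0, 40.0, order=4).samples
    deriv = np.gradient(bp) * fs
    sq = deriv * deriv
    integ = moving_mean(sq, window_samples(0.150, fs))

    refractory = int(round(0.2 * fs))
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        warnings.warn("no QRS candidates found; returning an empty R-peak train")
        return RPeakTrain(np.empty(0, dtype=int), fs, low_confidence=True)

    # adaptive thresholds (classic learning rates)
    lead = integ[: int(2 * fs)]
    spki = 0.25 * float(np.max(lead))
    npki = 0.5 * float(np.mean(lead))
    peaks: list[int] = []
    rr_hist: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        p = integ[c]
        if p > threshold():
            if peaks and (c - peaks[-1]) < refractory:
                if p > integ[peaks[-1]]:
                    peaks[-1] = int(c)
                continue
            # search-back: a long gap hides a missed beat
            if peaks and rr_hist:
                rr_avg = float(np.mean(rr_hist[-8:]))
                gap = c - peaks[-1]
                if gap > 1.66 * rr_avg:
                    lo, hi = peaks[-1] + refractory, c - refractory
                    inner = cand[(cand > lo) & (cand < hi)]
                    if inner.size:
                        b = int(inner[np.argmax(integ[inner])])
                        if integ[b] > 0.5 * threshold():
                            rr_hist.append(b - peaks[-1])
                            peaks.append(b)
                            spki = 0.25 * integ[b] + 0.75 * spki
            if peaks:
                rr_hist.append(c - peaks[-1])
            peaks.append(int(c))
            spki = 0.125 * p + 0.875 * spki
        else:
            npki = 0.125 * p + 0.875 * npki

    if not peaks:
        warnings.warn("no peaks exceeded the adaptive threshold")
        return RPeakTrain(np.empty(0, dtype=int), fs, low_confidence=True)

    # refine to the local extremum of the 5-40 Hz signal within +/-40 ms
    half = int(round(0.040 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(bp.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # enforce the refractory period after refinement (keep the larger peak)
    kept: list[int] = []
    for p in refined:
        if kept and p - kept[-1] < refractory:
            if np.abs(bp[p]) > np.abs(bp[kept[-1]]):
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    idx = np.asarray(kept, dtype=int)

    rate_bpm = 60.0 * idx.size / record.duration
    low_conf = not (30.0 <= rate_bpm <= 200.0) or spki < 4.0 * npki
    return RPeakTrain(idx, fs, low_confidence=low_conf)


def ecg_exclusion_mask(rpeaks: RPeakTrain, n_samples: int) -> SampleMask:
    """Keep-mask that excludes [r - 135 ms, r + 365 ms] around each R-peak.

    Window bounds are integer sample offsets (round-half-even) and both
    endpoints are inclusive; overlapping windows merge naturally.
    """
    fs = rpeaks.sampling_rate
    pre = int(np.round(0.135 * fs))
    post = int(np.round(0.365 * fs))
    keep = np.ones(n_samples, dtype=bool)
    for r in rpeaks.indices:
        if r >= n_samples:
            raise ValueError("R-peak index beyond record length")
        a = max(0, r - pre)
        b = min(n_samples - 1, r + post)
        keep[a:b + 1] = False
    return SampleMask(keep)


def _intervals_to_bool(intervals, n: int, fs: float) -> np.ndarray:
    out = np.zeros(n, dtype=bool)
    for onset, offset in intervals:
        a = int(np.clip(np.round(onset * fs), 0, n))
        b = int(np.clip(np.round(offset * fs), 0, n))
        out[a:b + 1] = True
    return out


def compute_i2bsnr(record: Record, cycles, mask: SampleMask | None = None,
                   epoch_length: float = 30.0) -> I2BSNRSeries:
    """Inspiratory-to-basal SNR per epoch, in dB.

    Within each ``epoch_length`` (default 30 s) epoch, inspiratory samples
    are those inside any cycle's [onset, offset] interval and kept by the
    cardiac exclusion mask; basal samples are those outside every cycle and
    kept by the mask.  Epochs with less than 250 ms of either class are
    flagged missing (NaN).

    ``cycles`` may be objects with ``onset``/``offset`` attributes (seconds)
    or plain ``(onset, offset)`` pairs.
    """
    if record.n_samples == 0:
        raise ValueError("empty record")
    fs = record.sampling_rate
    n = record.n_samples
    keep = mask.keep if mask is not None else np.ones(n, dtype=bool)
    if keep.size != n:
        raise ValueError("mask length must match record length")

    pairs = []
    for c in cycles:
        if hasattr(c, "onset"):
            if c.onset is None or c.offset is None:
                continue
            pairs.append((float(c.onset), float(c.offset)))
        else:
            pairs.append((float(c[0]), float(c[1])))
    pairs.sort()
    insp = _intervals_to_bool(pairs, n, fs)

    min_samples = int(np.ceil(0.250 * fs))
    epoch_n = int(round(epoch_length * fs))
    n_epochs = int(np.ceil(n / epoch_n))
    starts = np.arange(n_epochs) * epoch_length
    vals = np.full(n_epochs, np.nan)
    x = record.samples
    for k in range(n_epochs):
        sl = slice(k * epoch_n, min((k + 1) * epoch_n, n))
        ki = insp[sl] & keep[sl]
        kb = ~insp[sl] & keep[sl]
        if ki.sum() < min_samples or kb.sum() < min_samples:
            continue
        rms_i = np.sqrt(np.mean(x[sl][ki] ** 2))
        rms_b = np.sqrt(np.mean(x[sl][kb] ** 2))
        if rms_b > 0 and rms_i > 0:
            vals[k] = ratio_to_db(rms_i / rms_b)
    return I2BSNRSeries(starts, epoch_length, vals)
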