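"""Four cardiac-artifact suppression strategies for surface EMGdi.

All four preserve record length and sampling rate:

* :func:`wavelet_denoise` — db4 wavelet decomposition to level 4 with
  adaptive truncation of detail coefficients around each R-peak and the
  approximation band discarded,
* :func:`gate` — 45 Hz high-pass followed by replacement of a 130 ms window
  centered on each R-peak with a line joining the flanking RMS levels,
* :func:`adaptive_cancel` — LMS adaptive noise cancellation against a
  self-synthesized cardiac reference (averaged beat template tiled at the
  detected R-peaks),
* :func:`adaptive_then_gate` — the LMS canceller followed by gating with
  the high-pass stage disabled (the canceller already removed the
  low-frequency cardiac waves).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from ._dwt import wavedec, waverec
from ._kernels import lms_filter
from .preprocess import Record, RPeakTrain

__all__ = ["wavelet_denoise", "gate", "adaptive_cancel", "adaptive_then_gate"]

#: adaptive-threshold window bounds around each R-peak, seconds
WAVELET_LB = 0.200
WAVELET_UB = 0.300
WAVELET_K = 5.0
WAVELET_LEVEL = 4


def _robust_scale(values: np.ndarray) -> float:
    """1.4826 x median absolute deviation (consistent with a Gaussian SD)."""
    if values.size == 0:
        return 0.0
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def wavelet_denoise(record: Record, rpeaks: RPeakTrain) -> Record:
    """Adaptive wavelet thresholding of cardiac interference (db4, level 4).

    The level-4 approximation (content below fs/32, e.g. 15.625 Hz at
    500 Hz — mostly P/T waves) is zeroed.  Within a window centered on each
    R-peak, whose length grows from 200 ms at level 1 to 300 ms at level 4,
    detail coefficients whose magnitude exceeds ``K = 5`` times a robust
    scale estimate of the level's out-of-window coefficients are truncated
    to that bound.  Coefficients outside the windows are untouched.  With no
    usable R-peaks the truncation is applied globally, with a warning.
    """
    n = record.n_samples
    if n < 2 ** WAVELET_LEVEL * 2:
        raise ValueError("record too short for a 4-level decomposition")
    fs = record.sampling_rate
    coeffs = wavedec(record.samples, WAVELET_LEVEL)
    coeffs[0] = np.zeros_like(coeffs[0])  # discard the approximation band

    have_peaks = len(rpeaks) > 0
    if not have_peaks:
        warnings.warn("no R-peaks available; applying global wavelet thresholding")

    # coeffs[1:] are d_4, d_3, d_2, d_1
    for pos, d in enumerate(coeffs[1:]):
        level = WAVELET_LEVEL - pos
        dec = 2 ** level
        win_s = WAVELET_LB + (WAVELET_UB - WAVELET_LB) * (level - 1) / (
            WAVELET_LEVEL - 1)
        half = max(1, int(round(0.5 * win_s * fs / dec)))
        in_win = np.zeros(d.size, dtype=bool)
        if have_peaks:
            centers = rpeaks.indices // dec
            for c in centers:
                in_win[max(0, c - half):min(d.size, c + half + 1)] = True
        else:
            in_win[:] = True
        out = d[~in_win] if (~in_win).any() else d
        thr = WAVELET_K * _robust_scale(out)
        if thr > 0:
            coeffs[1 + pos] = np.where(in_win, np.clip(d, -thr, thr), d)
        elif not have_peaks:
            coeffs[1 + pos] = d
    y = waverec(coeffs, n)
    return record.replace(y)


def _window_rms(x: np.ndarray, a: int, b: int) -> float:
    """RMS of x[a:b] with bounds clipped to the record; NaN when empty."""
    a, b = max(0, a), min(x.size, b)
    if b <= a:
        return float("nan")
    return float(np.sqrt(np.mean(x[a:b] ** 2)))


def gate(record: Record, rpeaks: RPeakTrain,
         highpass: float | None = 45.0) -> Record:
    """Replace a 130 ms window around each R-peak with a flank-RMS line.

    After an optional zero-phase 2nd-order Butterworth high-pass at 45 Hz
    (pass ``highpass=None`` to skip, as in :func:`adaptive_then_gate`), the
    samples in the centered 130 ms window are replaced by the straight line
    joining the RMS of the 65 ms window immediately before and the RMS of
    the 65 ms window immediately after.  The replacement is the nonnegative
    RMS magnitude itself — downstream consumers are amplitude envelopes.
    Windows extending past the record edges shrink to what is available.
    """
    fs = record.sampling_rate
    if highpass is not None:
        sos = sps.butter(2, highpass, btype="highpass", fs=fs, output="sos")
        y = sps.sosfiltfilt(sos, record.samples)
    else:
        y = record.samples.astype(float).copy()
    half = int(np.round(0.065 * fs))
    for r in rpeaks.indices:
        a = max(0, r - half)
        b = min(y.size - 1, r + half)
        if b < a:
            continue
        rms_pre = _window_rms(y, a - half, a)
        rms_post = _window_rms(y, b + 1, b + 1 + half)
        if np.isnan(rms_pre):
            rms_pre = rms_post
        if np.isnan(rms_post):
            rms_post = rms_pre
        if np.isnan(rms_pre):
            continue
        y[a:b + 1] = np.linspace(rms_pre, rms_post, b - a + 1)
    return record.replace(y)


def _beat_segments(x: np.ndarray, rpeaks: RPeakTrain,
                   fs: float) -> tuple[np.ndarray, int]:
    pre = int(round(0.200 * fs))
    post = int(round(0.400 * fs))
    seg_len = pre + post
    segs = []
    for r in rpeaks.indices:
        a, b = r - pre, r + post
        if a >= 0 and b <= x.size:
            segs.append(x[a:b])
    return np.asarray(segs), pre


def adaptive_cancel(record: Record, rpeaks: RPeakTrain,
                    energy_tol: float = 0.05, max_evals: int = 12,
                    max_restarts: int = 5) -> Record:
    """LMS adaptive cancellation with a self-synthesized cardiac reference.

    A beat template is the average of the [-200, +400] ms segments around
    each R-peak after discarding the 25 % highest-energy segments (those
    with the most inspiratory EMG).  The template is tiled at every R-peak
    (later copies overwrite overlaps) to form the reference input; an LMS
    filter with 0.4 s of weights adapts against it, and the adaptation
    constant is searched (bisection on the log-step, at most ``max_evals``
    evaluations) until the cancellation-output energy matches the reference
    energy within ``energy_tol``.  Returns the residual (primary minus
    cancellation).  If the residual energy ever exceeds the input energy the
    step is halved and the run restarted, at most ``max_restarts`` times.
    """
    fs = record.sampling_rate
    x = record.samples.astype(float)
    if len(rpeaks) < 8:
        raise ValueError("adaptive cancellation needs at least 8 R-peaks")
    segs, pre = _beat_segments(x, rpeaks, fs)
    if segs.shape[0] < 8:
        raise ValueError("fewer than 8 complete beat segments available")
    energies = np.sum(segs ** 2, axis=1)
    n_keep = segs.shape[0] - int(np.ceil(0.25 * segs.shape[0]))
    keep = np.argsort(energies)[:n_keep]
    template = segs[keep].mean(axis=0)

    ref = np.zeros_like(x)
    for r in rpeaks.indices:
        a = r - pre
        b = a + template.size
        ta, tb = max(0, -a), template.size - max(0, b - x.size)
        ref[max(0, a):min(b, x.size)] = template[ta:tb]  # overwrite overlaps

    m = int(round(0.4 * fs))
    ref_energy = float(np.sum(ref ** 2))
    x_energy = float(np.sum(x ** 2))
    if ref_energy == 0:
        return record.replace(x.copy())
    # normalized step: mu_raw = mu / (m * reference power)
    norm = m * ref_energy / ref.size

    def run(mu: float) -> tuple[np.ndarray, np.ndarray]:
        return lms_filter(x, ref, m, mu / norm)

    lo, hi = np.log10(1e-4), np.log10(0.5)
    best = None
    best_err = np.inf
    log_mu = np.log10(0.05)
    restarts = 0
    for _ in range(max_evals):
        y, e = run(10.0 ** log_mu)
        if float(np.sum(e ** 2)) > x_energy:  # divergence guard
            restarts += 1
            hi = log_mu
            log_mu -= np.log10(2.0)
            if restarts > max_restarts:
                break
            continue
        ratio = float(np.sum(y ** 2)) / ref_energy
        err = abs(ratio - 1.0)
        if err < best_err:
            best, best_err = e, err
        if err <= energy_tol:
            break
        if ratio < 1.0:
            lo = log_mu
        else:
            hi = log_mu
        log_mu = 0.5 * (lo + hi)
    if best is None:
        warnings.warn("LMS did not stabilize; returning the unfiltered record")
        best = x.copy()
    elif best_err > energy_tol:
        warnings.warn(
            f"LMS energy-match criterion not met (best |ratio-1| = "
            f"{best_err:.3f}); keeping the closest step")
    return record.replace(best)


def adaptive_then_gate(record: Record, rpeaks: RPeakTrain) -> Record:
    """Adaptive cancellation followed by gating without the 45 Hz high-pass.

    The LMS stage replaces the high-pass (it removes the low-frequency
    cardiac waves); the gating geometry is unchanged (130 ms windows,
    65 ms flanks).
    """
    return gate(adaptive_cancel(record, rpeaks), rpeaks, highpass=None)
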