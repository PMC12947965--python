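"""Amplitude and complexity envelopes of the conditioned EMGdi signal.

Two envelope families, three stages each:

* **e1** — a 250 ms centered sliding window of either the RMS amplitude or
  the fixed sample entropy (fSE, embedding dimension m = 1, tolerance
  r = 0.4 x the SD of the whole preprocessed record).  Fixing r globally is
  what makes the entropy envelope track the random inspiratory EMG while
  staying nearly blind to the repetitive, deterministic cardiac artifact.
* **e2** — e1 smoothed with a 300 ms moving average (about one QRS width).
* **e3** — base-10 exponential of the Min-Max-normalized e2, which expands
  high-amplitude excursions relative to residual cardiac ripple; values lie
  in [1, 10].

All stages are sample-aligned with the source record (centered windows with
edge shrinkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kernels import fse_pair_counts
from ._windows import centered_halves, moving_mean, moving_rms, window_samples
from .preprocess import Record

__all__ = [
    "Envelope",
    "FseParams",
    "rms_envelope",
    "fse_envelope",
    "smooth_envelope",
    "exp_envelope",
    "compute_envelope",
]

#: ECG-suppression sources compatible with the entropy envelope.  Gating and
#: wavelet thresholding overwrite/truncate samples around each QRS, which
#: destroys the local randomness fSE measures and carves spurious notches.
FSE_COMPATIBLE_SOURCES = ("none", "adaptive")

SOURCE_METHODS = ("none", "wavelet", "gating", "adaptive", "adaptive_gating")


@dataclass
class Envelope:
    """A derived amplitude/complexity trace, sample-aligned with its source."""

    values: np.ndarray
    sampling_rate: float
    method: str            # "rms" | "fse"
    stage: str             # "e1" | "e2" | "e3"
    source_method: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite")
        if self.method not in ("rms", "fse"):
            raise ValueError("method must be 'rms' or 'fse'")
        if self.stage not in ("e1", "e2", "e3"):
            raise ValueError("stage must be one of e1, e2, e3")
        if self.source_method not in SOURCE_METHODS:
            raise ValueError(f"unknown source_method {self.source_method!r}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


@dataclass(frozen=True)
class FseParams:
    """Fixed-sample-entropy parameters.

    ``r`` is the fixed tolerance; when None it is computed once per record
    as 0.4 x the standard deviation of the preprocessed signal (never per
    window — that is the "fixed" in fixed sample entropy).
    """

    m: int = 1
    r: Optional[float] = None
    window_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r is not None and self.r <= 0:
            raise ValueError("tolerance r must be > 0")


def rms_envelope(record: Record, window_ms: float = 250.0,
                 source_method: str = "none") -> Envelope:
    """Stage-e1 RMS envelope over a centered ``window_ms`` sliding window."""
    if record.n_samples == 0:
        raise ValueError("empty record")
    w = window_samples(window_ms / 1000.0, record.sampling_rate)
    if w < 2:
        raise ValueError("window must contain at least 2 samples")
    vals = moving_rms(record.samples, w)
    return Envelope(vals, record.sampling_rate, "rms", "e1", source_method)


def fse_envelope(record: Record, params: FseParams | None = None,
                 source_method: str = "none") -> Envelope:
    """Stage-e1 fixed-sample-entropy envelope.

    Per centered window, the sample entropy -ln(A/B) is computed with a
    tolerance fixed for the whole record, where B counts template pairs of
    length m = 1 within r of each other and A the pairs that still match
    when extended by one sample.  Windows with no length-2 match (A = 0)
    take the ceiling ln(B (B-1)); windows with no match at all carry the
    nearest defined value.
    """
    if source_method not in FSE_COMPATIBLE_SOURCES:
        raise ValueError(
            f"fSE envelopes are not defined for source_method="
            f"{source_method!r}: gating and wavelet thresholding distort the "
            "random signal components the entropy measures (use 'none' or "
            "'adaptive')")
    if record.n_samples == 0:
        raise ValueError("empty record")
    params = params or FseParams()
    if params.m != 1:
        raise NotImplementedError("only embedding dimension m = 1 is supported")
    fs = record.sampling_rate
    w = window_samples(params.window_ms / 1000.0, fs)
    if w < 10:
        raise ValueError("fSE window must contain at least 10 samples")
    r = params.r if params.r is not None else 0.4 * float(np.std(record.samples))
    if r <= 0:
        raise ValueError("tolerance r must be > 0 (constant record?)")
    left, _ = centered_halves(w)
    A, B = fse_pair_counts(record.samples.astype(float), w, left, r)

    vals = np.full(record.n_samples, np.nan)
    ok = (A > 0) & (B > 0)
    vals[ok] = -np.log(A[ok] / B[ok])
    ceil = ~ok & (B >= 2)
    vals[ceil] = np.log(B[ceil] * (B[ceil] - 1.0))
    if np.isnan(vals).any():
        defined = np.flatnonzero(~np.isnan(vals))
        if defined.size == 0:
            warnings.warn("fSE undefined everywhere; returning zeros")
            vals[:] = 0.0
        else:
            # carry the nearest defined neighbor into the gaps
            idx = np.arange(vals.size)
            nearest = defined[np.searchsorted(defined, idx).clip(0, defined.size - 1)]
            prev = defined[np.maximum(np.searchsorted(defined, idx, "right") - 1, 0)]
            pick = np.where(np.abs(prev - idx) <= np.abs(nearest - idx), prev, nearest)
            vals = vals[pick]
    return Envelope(vals, fs, "fse", "e1", source_method)


def smooth_envelope(e1: Envelope, window_ms: float = 300.0) -> Envelope:
    """Stage e2: centered moving average of e1 (edges shrink)."""
    w = window_samples(window_ms / 1000.0, e1.sampling_rate)
    vals = moving_mean(e1.values, w)
    return Envelope(vals, e1.sampling_rate, e1.method, "e2", e1.source_method)


def exp_envelope(e2: Envelope) -> Envelope:
    """Stage e3: base-10 exponential of the Min-Max-normalized e2.

    Normalization is per record, so e3 is unit-free and bounded in [1, 10];
    the transform is strictly monotone in e2.  A constant e2 yields an
    all-ones envelope with a warning.
    """
    v = e2.values
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        warnings.warn("constant e2 envelope; e3 is identically 1")
        vals = np.ones_like(v)
    else:
        vals = 10.0 ** ((v - lo) / (hi - lo))
    return Envelope(vals, e2.sampling_rate, e2.method, "e3", e2.source_method)


def compute_envelope(record: Record, method: str, stage: str,
                     source_method: str = "none",
                     fse_params: FseParams | None = None) -> Envelope:
    """Build the requested envelope stage from a conditioned record."""
    if method == "rms":
        env = rms_envelope(record, source_method=source_method)
    elif method == "fse":
        env = fse_envelope(record, fse_params, source_method=source_method)
    else:
        raise ValueError("method must be 'rms' or 'fse'")
    if stage == "e1":
        return env
    env = smooth_envelope(env)
    if stage == "e2":
        return env
    if stage == "e3":
        return exp_envelope(env)
    raise ValueError("stage must be one of e1, e2, e3")
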