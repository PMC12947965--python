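"""Centered sliding-window primitives shared by filters and envelopes.

All moving windows in this package are centered: a window of ``w`` samples
around sample ``k`` covers ``[k - left, k + right]`` with ``left = w // 2``
and ``right = w - 1 - left`` (even counts take the extra sample on the
left).  At the record edges the window shrinks to the available samples.
"""

from __future__ import annotations

import numpy as np


def window_samples(duration_s: float, fs: float) -> int:
    """Number of samples in a window of ``duration_s`` seconds (>= 1)."""
    w = int(np.round(duration_s * fs))
    return max(w, 1)


def centered_halves(w: int) -> tuple[int, int]:
    left = w // 2
    return left, w - 1 - left


def sliding_sum(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered sliding sum with edge shrinkage.

    Returns ``(sums, counts)`` where ``counts[k]`` is the number of samples
    actually inside the (possibly clipped) window centered on ``k``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    left, right = centered_halves(w)
    c = np.concatenate(([0.0], np.cumsum(x)))
    k = np.arange(n)
    i0 = np.maximum(k - left, 0)
    i1 = np.minimum(k + right + 1, n)
    return c[i1] - c[i0], (i1 - i0).astype(float)


def moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    s, cnt = sliding_sum(x, w)
    return s / cnt


def moving_rms(x: np.ndarray, w: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    s, cnt = sliding_sum(x * x, w)
    # guard tiny negative round-off from the cumsum difference
    return np.sqrt(np.maximum(s / cnt, 0.0))
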