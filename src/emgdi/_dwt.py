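"""Minimal orthogonal discrete wavelet transform (Daubechies db4).

Only what the cardiac-artifact wavelet denoiser needs: multi-level analysis
and synthesis with the 8-tap db4 filter pair in periodization mode (circular
convolution, half-length subbands, perfect reconstruction for even lengths;
odd lengths are extended by repeating the final sample).
"""

from __future__ import annotations

import numpy as np

# db4 decomposition low-pass filter (8 taps, unit energy)
DB4_DEC_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
# quadrature mirror high-pass: g[k] = (-1)^k h[L-1-k]
DB4_DEC_HI = (-1.0) ** np.arange(8) * DB4_DEC_LO[::-1]


def _dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step; returns (approximation, detail)."""
    if x.size % 2:
        x = np.concatenate([x, x[-1:]])
    n = x.size
    L = DB4_DEC_LO.size
    k = np.arange(n // 2)
    idx = (2 * k[:, None] + 1 - np.arange(L)[None, :]) % n
    xs = x[idx]
    return xs @ DB4_DEC_LO, xs @ DB4_DEC_HI


def _idwt_step(a: np.ndarray, d: np.ndarray, out_len: int) -> np.ndarray:
    """One periodized synthesis step, inverse of :func:`_dwt_step`."""
    half = a.size
    n = 2 * half
    L = DB4_DEC_LO.size
    k = np.arange(half)
    idx = (2 * k[:, None] + 1 - np.arange(L)[None, :]) % n
    contrib = DB4_DEC_LO[None, :] * a[:, None] + DB4_DEC_HI[None, :] * d[:, None]
    x = np.zeros(n)
    np.add.at(x, idx, contrib)
    return x[:out_len]


def wavedec(x: np.ndarray, level: int) -> list[np.ndarray]:
    """Multi-level db4 decomposition: ``[a_L, d_L, d_{L-1}, ..., d_1]``."""
    a = np.asarray(x, dtype=float)
    coeffs: list[np.ndarray] = []
    for _ in range(level):
        a, d = _dwt_step(a)
        coeffs.append(d)
    coeffs.append(a)
    coeffs.reverse()
    return coeffs


def waverec(coeffs: list[np.ndarray], out_len: int) -> np.ndarray:
    """Inverse of :func:`wavedec`; ``out_len`` is the original signal length."""
    a = coeffs[0]
    details = coeffs[1:]
    lengths = []
    n = out_len
    for _ in details:
        lengths.append(n)
        n = (n + 1) // 2
    for d, ln in zip(details, reversed(lengths)):
        a = _idwt_step(a, d, ln)
    return a
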