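"""Numba kernels for the two sequential hot loops.

Pure-Python equivalents of both loops exist in the test suite as brute-force
oracles; these compiled versions are the production path.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lms_filter(x, ref, m, mu):
    """Least-mean-squares adaptive canceller.

    ``x`` is the primary input, ``ref`` the reference (the tiled cardiac
    template train), ``m`` the number of filter weights and ``mu`` the raw
    adaptation constant (caller normalizes by reference power).  Returns
    ``(y, e)``: the cancellation output and the residual ``x - y``.

    The reference is zero outside beat windows, so the weight update is
    skipped wherever the last ``m`` reference samples are all zero.
    """
    n = x.size
    w = np.zeros(m)
    y = np.zeros(n)
    e = np.empty(n)
    active_until = -1
    for i in range(n):
        if ref[i] != 0.0:
            active_until = i + m
        if i >= active_until and active_until >= 0:
            e[i] = x[i]
            continue
        if active_until < 0:
            e[i] = x[i]
            continue
        kmax = m if i + 1 >= m else i + 1
        acc = 0.0
        for k in range(kmax):
            acc += w[k] * ref[i - k]
        y[i] = acc
        e[i] = x[i] - acc
        f = 2.0 * mu * e[i]
        for k in range(kmax):
            w[k] += f * ref[i - k]
    return y, e


@njit(cache=True)
def _direct_pair_counts(x, s, e, r):
    """Template pair counts over window ``x[s:e]`` (m = 1 convention).

    Templates of length 1 are ``x[i]`` for ``i`` in ``[s, e-2]`` (the last
    sample only serves as a successor), so the conditional probability A/B is
    well defined and equals 1 for a constant window.
    """
    a = 0
    b = 0
    for i in range(s, e - 1):
        for j in range(i + 1, e - 1):
            if abs(x[i] - x[j]) <= r:
                b += 1
                if abs(x[i + 1] - x[j + 1]) <= r:
                    a += 1
    return a, b


@njit(cache=True)
def fse_pair_counts(x, w, left, r):
    """Sliding-window sample-entropy pair counts (m = 1, fixed tolerance r).

    For every center position ``k`` the window is ``[k-left, k+left+...]``
    clipped to the record; full interior windows are updated incrementally in
    O(w) per step, edge windows are counted directly.  Returns float arrays
    ``(A, B)`` of matching template pairs of length 2 and 1 respectively.
    """
    n = x.size
    right = w - 1 - left
    A = np.zeros(n)
    B = np.zeros(n)
    if n == 0:
        return A, B
    # edge positions (clipped windows) by direct enumeration
    for k in range(n):
        if k - left < 0 or k + right > n - 1:
            s = k - left
            if s < 0:
                s = 0
            e = k + right + 1
            if e > n:
                e = n
            a, b = _direct_pair_counts(x, s, e, r)
            A[k] = a
            B[k] = b
    if n < w:
        return A, B
    # full windows: incremental pair counts over template range [s, s+w-2]
    s0 = 0
    a_cur, b_cur = _direct_pair_counts(x, s0, s0 + w, r)
    A[left] = a_cur
    B[left] = b_cur
    a_run = float(a_cur)
    b_run = float(b_cur)
    for s in range(1, n - w + 1):
        old = s - 1            # departing template index
        new = s + w - 2        # arriving template index
        for j in range(s, s + w - 2):
            if abs(x[old] - x[j]) <= r:
                b_run -= 1.0
                if abs(x[old + 1] - x[j + 1]) <= r:
                    a_run -= 1.0
        for i in range(s, s + w - 2):
            if abs(x[i] - x[new]) <= r:
                b_run += 1.0
                if abs(x[i + 1] - x[new + 1]) <= r:
                    a_run += 1.0
        A[s + left] = a_run
        B[s + left] = b_run
    return A, B
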