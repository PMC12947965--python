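"""Inspiratory cycle detection and onset/offset localization.

Event detection compares two centered moving averages of the envelope: a
slow 3 s average tracking the baseline and a fast 1 s average tracking the
respiratory component.  Every maximal run where the fast average exceeds the
slow one is a candidate cycle, annotated at the temporal midpoint of the
run.  Candidates then pass through:

1. a duration filter (< 200 ms rejected),
2. an amplitude filter (mean envelope inside the run must exceed the mean
   in two flanking windows of 20 % of the run duration by at least 10 %),
3. onset/offset localization against adaptive thresholds — the KDE mode of
   the envelope between the current marker and the neighboring markers —
   scanning outward from the marker to the last sample above threshold,
4. a Shannon-entropy plausibility filter (the envelope distribution inside
   a genuine burst is broader than in the adjacent between-burst phases).

Rejected candidates are kept in the returned lists with explanatory flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from ._windows import moving_mean, window_samples
from .envelopes import Envelope

__all__ = [
    "CycleInterval",
    "DetectorConfig",
    "detect_events",
    "amplitude_filter",
    "localize_onset_offset",
    "entropy_filter",
    "detect_cycles",
]

REJECT_FLAGS = frozenset({"duration_reject", "amplitude_reject", "entropy_reject"})


@dataclass
class CycleInterval:
    """One detected inspiratory effort (times in seconds).

    ``start``/``end`` are the provisional moving-average crossing bounds;
    ``onset``/``offset`` are filled by :func:`localize_onset_offset`.
    """

    marker: float
    onset: Optional[float] = None
    offset: Optional[float] = None
    flags: set = field(default_factory=set)
    start: Optional[float] = None
    end: Optional[float] = None
    onset_corrected: Optional[float] = None
    offset_corrected: Optional[float] = None

    @property
    def accepted(self) -> bool:
        return not (self.flags & REJECT_FLAGS)

    @property
    def duration(self) -> Optional[float]:
        if self.onset is None or self.offset is None:
            return None
        return self.offset - self.onset


@dataclass(frozen=True)
class DetectorConfig:
    slow_ma: float = 3.0
    fast_ma: float = 1.0
    min_cycle: float = 0.2
    amplitude_margin: float = 0.10
    flank_fraction: float = 0.20
    kde_bandwidth: str = "silverman"
    entropy_bins: int = 32

    def __post_init__(self) -> None:
        if not self.fast_ma < self.slow_ma:
            raise ValueError("fast_ma must be shorter than slow_ma")
        for name in ("amplitude_margin", "flank_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def detect_events(env: Envelope, cfg: DetectorConfig | None = None
                  ) -> list[CycleInterval]:
    """Dual moving-average event detection (markers + provisional bounds)."""
    cfg = cfg or DetectorConfig()
    fs = env.sampling_rate
    n = env.n_samples
    w_slow = window_samples(cfg.slow_ma, fs)
    if n <= w_slow:
        raise ValueError("envelope shorter than the slow moving-average window")
    fast = moving_mean(env.values, window_samples(cfg.fast_ma, fs))
    slow = moving_mean(env.values, w_slow)
    above = fast > slow

    # maximal runs of fast > slow
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [n - 1]))

    events: list[CycleInterval] = []
    for i0, i1 in zip(starts, ends):
        t0, t1 = i0 / fs, i1 / fs
        ev = CycleInterval(marker=0.5 * (t0 + t1), start=t0, end=t1)
        if i0 == 0 or i1 == n - 1:
            ev.flags.add("edge")
        if t1 - t0 < cfg.min_cycle:
            ev.flags.add("duration_reject")
        events.append(ev)
    return events


def amplitude_filter(events: list[CycleInterval], env: Envelope,
                     cfg: DetectorConfig | None = None) -> list[CycleInterval]:
    """Reject candidates whose envelope barely rises above the flanks.

    The mean envelope inside the provisional interval must exceed the pooled
    mean over two flanking windows (each ``flank_fraction`` of the interval
    duration, immediately before and after) by more than
    ``amplitude_margin`` (10 %).  Flanks clipped by the record edge shrink
    and set the ``edge`` flag.
    """
    cfg = cfg or DetectorConfig()
    fs = env.sampling_rate
    v = env.values
    n = v.size
    for ev in events:
        if "duration_reject" in ev.flags:
            continue
        i0 = int(round(ev.start * fs))
        i1 = int(round(ev.end * fs))
        fw = max(1, int(round(cfg.flank_fraction * (i1 - i0 + 1))))
        inside = v[i0:i1 + 1]
        a0, b1 = i0 - fw, i1 + 1 + fw
        if a0 < 0 or b1 > n:
            ev.flags.add("edge")
        flank = np.concatenate((v[max(0, a0):i0], v[i1 + 1:min(n, b1)]))
        if flank.size == 0:
            ev.flags.add("amplitude_reject")
            continue
        if np.mean(inside) < (1.0 + cfg.amplitude_margin) * np.mean(flank):
            ev.flags.add("amplitude_reject")
    return events


def _kde_mode(values: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a 1-D sample via Gaussian KDE (Silverman bandwidth).

    Degenerate segments (constant, or too short for a KDE) return the
    segment value plus a tiny epsilon, so that no sample exceeds it and the
    dependent event is rejected downstream.
    """
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo or values.size < 3:
        return lo + 1e-12
    try:
        kde = stats.gaussian_kde(values, bw_method="silverman")
    except np.linalg.LinAlgError:
        return lo + 1e-12
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[np.argmax(kde(grid))])


def localize_onset_offset(events: list[CycleInterval], env: Envelope,
                          cfg: DetectorConfig | None = None
                          ) -> list[CycleInterval]:
    """Fill onset/offset by scanning from each marker against KDE thresholds.

    The onset threshold of a cycle is the KDE mode of the envelope between
    the previous accepted marker (or the record start) and the current
    marker; the offset threshold is the mode between the current marker and
    the next accepted marker (or the record end).  Scanning backward
    (forward) from the marker, the onset (offset) is the last sample whose
    value exceeds the threshold before the envelope first dips to or below
    it; the scan never crosses the neighboring marker.  Localized cycles
    shorter than 200 ms are rejected.
    """
    cfg = cfg or DetectorConfig()
    fs = env.sampling_rate
    v = env.values
    n = v.size
    accepted = [ev for ev in events if ev.accepted]
    markers = [int(round(ev.marker * fs)) for ev in accepted]
    for k, ev in enumerate(accepted):
        m = min(markers[k], n - 1)
        left_stop = markers[k - 1] if k > 0 else 0
        right_stop = markers[k + 1] if k + 1 < len(markers) else n - 1
        thr_on = _kde_mode(v[left_stop:m + 1])
        thr_off = _kde_mode(v[m:right_stop + 1])

        if v[m] <= thr_on or v[m] <= thr_off:
            ev.flags.add("duration_reject")
            continue
        i = m
        while i > left_stop and v[i - 1] > thr_on:
            i -= 1
        if i == left_stop:
            ev.flags.add("edge")
        j = m
        while j < right_stop and v[j + 1] > thr_off:
            j += 1
        if j == right_stop:
            ev.flags.add("edge")
        ev.onset = i / fs
        ev.offset = j / fs
        if ev.offset - ev.onset < cfg.min_cycle:
            ev.flags.add("duration_reject")
    return events


def _shannon_entropy(values: np.ndarray, bins: int, lo: float, hi: float) -> float:
    if values.size == 0:
        return float("nan")
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-np.sum(p * np.log(p)))


def entropy_filter(events: list[CycleInterval], env: Envelope,
                   cfg: DetectorConfig | None = None) -> list[CycleInterval]:
    """Reject cycles whose in-burst envelope distribution is too narrow.

    The Shannon entropy of the envelope histogram (32 equal-width bins over
    the pooled range of the three phases) between onset and offset must be
    at least that of both adjacent between-cycle phases; edge cycles are
    compared only against the side that exists.
    """
    cfg = cfg or DetectorConfig()
    fs = env.sampling_rate
    v = env.values
    n = v.size
    accepted = [ev for ev in events if ev.accepted and ev.onset is not None]
    for k, ev in enumerate(accepted):
        on = int(round(ev.onset * fs))
        off = int(round(ev.offset * fs))
        prev_off = int(round(accepted[k - 1].offset * fs)) if k > 0 else 0
        next_on = (int(round(accepted[k + 1].onset * fs))
                   if k + 1 < len(accepted) else n - 1)
        inside = v[on:off + 1]
        before = v[prev_off:on] if on > prev_off else np.empty(0)
        after = v[off + 1:next_on + 1] if next_on > off else np.empty(0)
        pooled = np.concatenate((inside, before, after))
        lo, hi = float(np.min(pooled)), float(np.max(pooled))
        if hi == lo:
            ev.flags.add("entropy_reject")
            continue
        h_in = _shannon_entropy(inside, cfg.entropy_bins, lo, hi)
        for phase in (before, after):
            if phase.size:
                if h_in < _shannon_entropy(phase, cfg.entropy_bins, lo, hi):
                    ev.flags.add("entropy_reject")
                    break
    return events


def detect_cycles(env: Envelope, cfg: DetectorConfig | None = None
                  ) -> tuple[list[CycleInterval], list[CycleInterval]]:
    """Full detection chain; returns ``(accepted, all_candidates)``."""
    cfg = cfg or DetectorConfig()
    events = detect_events(env, cfg)
    events = amplitude_filter(events, env, cfg)
    events = localize_onset_offset(events, env, cfg)
    events = entropy_filter(events, env, cfg)
    accepted = [ev for ev in events if ev.accepted]
    return accepted, events
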