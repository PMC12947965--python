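"""Reference construction and detection metrics.

Two independent expert scorers annotate inspiratory activity as
onset-offset intervals.  Overlapping intervals from the two scorers are
paired one-to-one (greedy by overlap length); a paired interval is a
*reliable event*.  Its onset marker is *reliable* when the scorers differ
by less than 150 ms, and likewise — independently — for the offset; the
reference time is the arithmetic mean of the two expert marks.

Event-level performance counts a detection as TP when it overlaps exactly
one reliable event (each event matchable once), an unmatched reliable event
as FN, and a detection overlapping neither a reliable nor an unreliable
(excluded) event as FP.  Timing metrics (mean difference, SD, RMSE) are
computed over TP pairs whose marker is reliable, with the population SD
convention so that ``rmse**2 == md**2 + sd**2`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AnnotationSet",
    "ReliableEvent",
    "MatchReport",
    "TimingReport",
    "MARKER_TOLERANCE",
    "greedy_overlap_pairs",
    "pair_scorers",
    "match_detections",
    "timing_metrics",
]

#: maximum inter-scorer discrepancy for a reliable marker, seconds (strict <)
MARKER_TOLERANCE = 0.150

Interval = tuple[float, float]


@dataclass
class AnnotationSet:
    """One scorer's onset-offset intervals (sorted, non-overlapping)."""

    scorer_id: str
    intervals: list

    def __post_init__(self) -> None:
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in self.intervals:
            if b <= a:
                raise ValueError("each interval needs offset > onset")
        for (_, b0), (a1, _) in zip(self.intervals, self.intervals[1:]):
            if a1 < b0:
                raise ValueError("intervals must be sorted and non-overlapping")


@dataclass
class ReliableEvent:
    """An inspiratory effort annotated (with overlap) by both scorers."""

    ref_onset: Optional[float]
    ref_offset: Optional[float]
    scorer_a: Interval
    scorer_b: Interval

    @property
    def interval(self) -> Interval:
        """Event extent used for overlap matching: the union of the two."""
        return (min(self.scorer_a[0], self.scorer_b[0]),
                max(self.scorer_a[1], self.scorer_b[1]))


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        se, pr = self.sensitivity, self.precision
        if not np.isfinite(se) or not np.isfinite(pr) or se + pr == 0:
            return float("nan")
        return 2 * se * pr / (se + pr)


@dataclass
class TimingReport:
    """Timing-error summary.  ``sd`` is the population SD (ddof = 0), so
    ``rmse**2 == md**2 + sd**2`` holds as an identity."""

    n: int
    md: float
    sd: float
    rmse: float
    empty: bool = False


def _overlap(a: Interval, b: Interval) -> float:
    return min(a[1], b[1]) - max(a[0], b[0])


def greedy_overlap_pairs(a: Sequence[Interval], b: Sequence[Interval]
                         ) -> list[tuple[int, int]]:
    """One-to-one pairing of overlapping intervals, greedy by overlap length.

    Any positive-length intersection counts as overlap (closed intervals).
    Candidates are taken in order of decreasing overlap; an interval already
    paired is skipped, which discards ambiguous many-to-one matches.
    Returns index pairs ``(i, j)`` sorted by ``i``.
    """
    cands = []
    for i, ia in enumerate(a):
        for j, jb in enumerate(b):
            ov = _overlap(ia, jb)
            if ov > 0:
                cands.append((ov, i, j))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return sorted(pairs)


def pair_scorers(a: AnnotationSet, b: AnnotationSet) -> list[ReliableEvent]:
    """Build the reliable-event reference from two scorers' annotations.

    Onset and offset reliability are decided independently: a marker is
    reliable iff the scorers differ by strictly less than 150 ms, in which
    case the reference is the mean of the two; an unreliable marker is
    recorded as None without invalidating the other marker.
    """
    pairs = greedy_overlap_pairs(a.intervals, b.intervals)
    events = []
    for i, j in pairs:
        ia, ib = a.intervals[i], b.intervals[j]
        ref_on = 0.5 * (ia[0] + ib[0]) if abs(ia[0] - ib[0]) < MARKER_TOLERANCE else None
        ref_off = 0.5 * (ia[1] + ib[1]) if abs(ia[1] - ib[1]) < MARKER_TOLERANCE else None
        events.append(ReliableEvent(ref_on, ref_off, ia, ib))
    return events


def _detection_interval(det) -> Optional[Interval]:
    """Extent of a detection: localized [onset, offset] if present, else the
    provisional crossing bounds."""
    if getattr(det, "onset", None) is not None and getattr(det, "offset", None) is not None:
        return (float(det.onset), float(det.offset))
    if getattr(det, "start", None) is not None and getattr(det, "end", None) is not None:
        return (float(det.start), float(det.end))
    if isinstance(det, (tuple, list)) and len(det) == 2:
        return (float(det[0]), float(det[1]))
    return None


def match_detections(detected: Sequence, reference: Sequence[ReliableEvent],
                     unreliable: Sequence[Interval] = ()) -> MatchReport:
    """Event-level TP/FP/FN counts against the reliable-event reference.

    ``unreliable`` holds the intervals excluded from the reference (single-
    scorer or ambiguous annotations): detections overlapping only those are
    ignored — they enter neither the TP nor the FP count.
    """
    det_iv = [iv for iv in (_detection_interval(d) for d in detected)
              if iv is not None]
    ref_iv = [ev.interval for ev in reference]
    pairs = greedy_overlap_pairs(det_iv, ref_iv)
    tp = len(pairs)
    fn = len(ref_iv) - tp
    matched = {i for i, _ in pairs}
    fp = 0
    for i, iv in enumerate(det_iv):
        if i in matched:
            continue
        if any(_overlap(iv, r) > 0 for r in ref_iv):
            continue  # extra detection on an already-matched event: ignored
        if any(_overlap(iv, u) > 0 for u in unreliable):
            continue  # touches only excluded annotations: ignored
        fp += 1
    return MatchReport(tp=tp, fp=fp, fn=fn)


def timing_metrics(detected: Sequence, reference: Sequence[ReliableEvent],
                   marker: str = "onset") -> TimingReport:
    """MD/SD/RMSE of ``detected - reference`` for one marker type.

    Only TP pairs whose reference marker is reliable contribute; the sign
    convention is detected minus reference (negative = detector early).
    """
    if marker not in ("onset", "offset"):
        raise ValueError("marker must be 'onset' or 'offset'")
    det_iv = [iv for iv in (_detection_interval(d) for d in detected)
              if iv is not None]
    ref_iv = [ev.interval for ev in reference]
    pairs = greedy_overlap_pairs(det_iv, ref_iv)
    side = 0 if marker == "onset" else 1
    diffs = []
    for i, j in pairs:
        ref_t = reference[j].ref_onset if marker == "onset" else reference[j].ref_offset
        if ref_t is None:
            continue
        diffs.append(det_iv[i][side] - ref_t)
    if not diffs:
        return TimingReport(0, float("nan"), float("nan"), float("nan"), empty=True)
    d = np.asarray(diffs)
    md = float(np.mean(d))
    sd = float(np.std(d))              # population SD: rmse^2 = md^2 + sd^2
    rmse = float(np.sqrt(np.mean(d * d)))
    return TimingReport(len(diffs), md, sd, rmse)
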