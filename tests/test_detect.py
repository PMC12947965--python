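"""Cycle detection, validity filters and onset/offset localization."""

import numpy as np
import pytest

from emgdi.detect import (CycleInterval, DetectorConfig, amplitude_filter,
                          detect_cycles, detect_events, entropy_filter,
                          localize_onset_offset)
from emgdi.envelopes import Envelope, compute_envelope

FS = 100.0  # envelope-level tests do not need the full EMG rate


def _env(values, fs=FS):
    return Envelope(np.asarray(values, dtype=float), fs, "rms", "e1")


def brute_force_events(values, fs, cfg):
    """Independent crossing-scan oracle: direct convolution moving averages
    and a sign-change scan of fast - slow."""
    def ma(x, w):
        out = np.empty_like(x)
        left = w // 2
        right = w - 1 - left
        for k in range(x.size):
            lo, hi = max(0, k - left), min(x.size, k + right + 1)
            out[k] = np.mean(x[lo:hi])
        return out

    fast = ma(values, int(round(cfg.fast_ma * fs)))
    slow = ma(values, int(round(cfg.slow_ma * fs)))
    diff = np.sign(fast - slow)
    events = []
    start = None
    for k in range(values.size):
        if diff[k] > 0 and start is None:
            start = k
        elif diff[k] <= 0 and start is not None:
            events.append((start, k - 1))
            start = None
    if start is not None:
        events.append((start, values.size - 1))
    return events


class TestDetectEvents:
    def test_flat_envelope_has_no_events(self):
        env = _env(np.full(2000, 1.0))
        assert detect_events(env) == []

    def test_single_burst_marker_at_center(self):
        v = np.full(3000, 0.5)
        t0 = 15.0
        v[int((t0 - 0.5) * FS):int((t0 + 0.5) * FS)] = 2.0
        events = detect_events(_env(v))
        kept = [e for e in events if e.accepted]
        assert len(kept) == 1
        # closed-form MAs of a rectangle are symmetric about its center
        assert kept[0].marker == pytest.approx(t0, abs=2.0 / FS)

    def test_too_short_envelope_rejected(self):
        with pytest.raises(ValueError, match="slow"):
            detect_events(_env(np.ones(100)))

    def test_sub_200ms_runs_flagged(self):
        # short moving averages keep the crossing run as narrow as the
        # burst, so the 200 ms duration rule can bite at this stage
        cfg = DetectorConfig(fast_ma=0.05, slow_ma=0.5)
        v = np.full(3000, 0.5)
        v[1500:1510] = 5.0  # 100 ms at fs 100
        events = detect_events(_env(v), cfg)
        assert events and all("duration_reject" in e.flags for e in events)

    @pytest.mark.parametrize("seed", range(6))
    def test_count_equals_crossing_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # smooth random envelope: cumulative noise, rectified
        v = np.abs(np.cumsum(rng.standard_normal(3000))) / 10 + 0.5
        cfg = DetectorConfig()
        mine = detect_events(_env(v), cfg)
        oracle = brute_force_events(v, FS, cfg)
        assert len(mine) == len(oracle)
        for ev, (s, e) in zip(mine, oracle):
            assert ev.start == pytest.approx(s / FS)
            assert ev.end == pytest.approx(e / FS)


class TestAmplitudeFilter:
    def _event(self, start, end):
        return CycleInterval(marker=0.5 * (start + end), start=start, end=end)

    def test_equal_means_rejected(self):
        v = np.full(1000, 1.0)
        ev = self._event(4.0, 5.0)
        amplitude_filter([ev], _env(v))
        assert "amplitude_reject" in ev.flags

    def test_twenty_percent_margin_kept(self):
        v = np.full(1000, 1.0)
        v[400:501] = 1.2
        ev = self._event(4.0, 5.0)
        amplitude_filter([ev], _env(v))
        assert ev.accepted

    def test_short_burst_rejected_regardless_of_amplitude(self):
        """A 150 ms burst, however large, never survives the full chain:
        the moving averages widen the crossing run past 200 ms, but the
        localized onset-offset span stays at the burst width."""
        from emgdi.detect import detect_cycles
        rng = np.random.default_rng(7)
        v = 0.1 + 0.02 * np.abs(rng.standard_normal(3000))
        v[1500:1515] = 1.0
        accepted, events = detect_cycles(_env(v))
        assert events  # the burst was seen ...
        assert not accepted  # ... and rejected

    def test_flank_at_edge_sets_edge_flag(self):
        v = np.full(1000, 1.0)
        v[0:101] = 2.0
        ev = self._event(0.0, 1.0)
        amplitude_filter([ev], _env(v))
        assert "edge" in ev.flags


class TestLocalization:
    def _trapezoid(self, baseline=0.2, peak=1.0, noise=0.01):
        rng = np.random.default_rng(0)
        v = np.full(4000, baseline) + noise * rng.standard_normal(4000)
        # ramp 14-15 s, plateau 15-17 s, ramp down 17-18 s
        t = np.arange(4000) / FS
        up = (t >= 14) & (t < 15)
        v[up] = baseline + (peak - baseline) * (t[up] - 14)
        v[(t >= 15) & (t < 17)] = peak
        dn = (t >= 17) & (t < 18)
        v[dn] = peak - (peak - baseline) * (t[dn] - 17)
        return v

    def test_trapezoid_edges_recovered(self):
        """With a baseline-mode threshold the onset/offset land at the
        geometric foot of the ramps, within a few envelope steps."""
        v = self._trapezoid()
        events = detect_events(_env(v))
        events = amplitude_filter(events, _env(v))
        events = localize_onset_offset(events, _env(v))
        kept = [e for e in events if e.accepted]
        assert len(kept) == 1
        ev = kept[0]
        assert ev.onset == pytest.approx(14.0, abs=0.15)
        assert ev.offset == pytest.approx(18.0, abs=0.15)

    def test_symmetric_burst_symmetric_marks(self):
        v = self._trapezoid()
        events = detect_events(_env(v))
        events = amplitude_filter(events, _env(v))
        events = localize_onset_offset(events, _env(v))
        ev = [e for e in events if e.accepted][0]
        assert (ev.marker - ev.onset) == pytest.approx(
            ev.offset - ev.marker, abs=2.0 / FS)

    def test_constant_segment_degenerates_to_rejection(self):
        v = np.full(2000, 1.0)
        ev = CycleInterval(marker=10.0, start=9.5, end=10.5)
        localize_onset_offset([ev], _env(v))
        assert "duration_reject" in ev.flags


class TestEntropyFilter:
    def _localized(self, on, off, marker=None):
        return CycleInterval(marker=marker or 0.5 * (on + off),
                             onset=on, offset=off, start=on, end=off)

    def test_flat_cycle_between_noisy_phases_rejected(self):
        rng = np.random.default_rng(1)
        v = 1.0 + 0.3 * rng.standard_normal(3000)
        v[1000:2001] = 2.0  # zero-entropy plateau
        ev = self._localized(10.0, 20.0)
        entropy_filter([ev], _env(v))
        assert "entropy_reject" in ev.flags

    def test_rich_cycle_between_flat_phases_kept(self):
        rng = np.random.default_rng(2)
        v = np.full(3000, 0.5)
        v[1000:2001] = 1.0 + 0.5 * rng.standard_normal(1001)
        ev = self._localized(10.0, 20.0)
        entropy_filter([ev], _env(v))
        assert ev.accepted


class TestClosedLoop:
    def test_every_true_cycle_found_once(self, clean_record_50):
        """High-SNR synthetic record, fSE-e3: exactly one accepted marker
        inside each true inspiration."""
        rec, truth = clean_record_50
        env = compute_envelope(rec, "fse", "e3")
        accepted, _ = detect_cycles(env)
        assert len(accepted) == truth.n_cycles
        for ev, (on, off) in zip(accepted, truth.intervals()):
            assert on <= ev.marker <= off

    def test_accepted_cycles_sorted_and_disjoint(self, clean_record_50):
        rec, truth = clean_record_50
        env = compute_envelope(rec, "rms", "e2")
        accepted, _ = detect_cycles(env)
        markers = [ev.marker for ev in accepted]
        assert markers == sorted(markers)
        for a, b in zip(accepted, accepted[1:]):
            assert a.offset <= b.onset + 1e-9
            assert a.onset < a.marker < a.offset
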