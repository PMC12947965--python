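"""Conditioning stages: filters, QRS detection, masks, I2BSNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from emgdi.preprocess import (I2BSNRSeries, Record, RPeakTrain, bandpass,
                              compute_i2bsnr, detect_r_peaks,
                              ecg_exclusion_mask, notch_mains, ratio_to_db)
from emgdi.synth import EcgSpec, SimulationSpec, simulate_emgdi

FS = 500.0


def _sine_record(freq, duration=20.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return Record(np.sin(2 * np.pi * freq * t), fs)


def _filtfilt_gain(low, high, order, fs, freq):
    """Analytic zero-phase gain: squared Butterworth magnitude response."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


class TestBandpass:
    def test_dc_rejection(self):
        rec = Record(np.full(5000, 3.7), FS)
        out = bandpass(rec)
        assert np.max(np.abs(out.samples)) < 1e-6

    @pytest.mark.parametrize("freq, tol", [(100.0, 0.01), (1.0, None)])
    def test_tone_gain_matches_response_oracle(self, freq, tol):
        rec = _sine_record(freq)
        out = bandpass(rec)
        # steady-state amplitude away from the edges, via RMS * sqrt(2)
        # (a sampled peak underestimates tones near fs/5)
        mid = slice(int(5 * FS), int(15 * FS))
        amp = np.sqrt(2.0) * float(np.sqrt(np.mean(out.samples[mid] ** 2)))
        expected = _filtfilt_gain(5, 200, 4, FS, freq)
        if tol is not None:
            assert amp == pytest.approx(1.0, abs=tol)
        assert amp == pytest.approx(expected, rel=0.02, abs=1e-4)
        if freq == 1.0:
            assert amp < 0.05

    def test_zero_phase_time_reversal_symmetry(self):
        # exact away from the edge transients of the finite record
        rng = np.random.default_rng(0)
        rec = Record(rng.standard_normal(4000), FS)
        fwd = bandpass(rec).samples
        rev = bandpass(Record(rec.samples[::-1], FS)).samples[::-1]
        np.testing.assert_allclose(fwd[1000:-1000], rev[1000:-1000],
                                   atol=1e-8)

    def test_nyquist_clipping_warns(self):
        rec = Record(np.random.default_rng(1).standard_normal(2000), 300.0)
        with pytest.warns(UserWarning, match="Nyquist"):
            bandpass(rec, 5, 200)

    def test_too_short_record_errors(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass(Record(np.zeros(10), FS))


class TestNotch:
    def test_strong_mains_removed_to_sideband_level(self):
        rng = np.random.default_rng(2)
        t = np.arange(int(60 * FS)) / FS
        x = rng.standard_normal(t.size) + 5.0 * np.sin(2 * np.pi * 50 * t)
        out = notch_mains(Record(x, FS))
        f, psd = sps.welch(out.samples, fs=FS, nperseg=int(4 * FS))
        p0 = np.mean(psd[np.abs(f - 50) <= 1])
        psb = 0.5 * (np.mean(psd[np.abs(f - 47) <= 1])
                     + np.mean(psd[np.abs(f - 53) <= 1]))
        assert abs(p0 / psb - 1.0) <= 0.15

    def test_clean_record_nearly_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(30 * FS))
        out = notch_mains(Record(x, FS))
        # total power loss from notching a mains-free record is negligible
        assert np.mean(out.samples ** 2) == pytest.approx(np.mean(x ** 2),
                                                          rel=0.02)

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            notch_mains(Record(np.zeros(1000), 200.0), 50.0, n_harmonics=3)


class TestRatioToDb:
    @pytest.mark.parametrize("ratio, db", [(1.0, 0.0), (1.2, 1.58), (10.0, 20.0)])
    def test_values(self, ratio, db):
        assert ratio_to_db(ratio) == pytest.approx(db, abs=0.005)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ratio_to_db(0.0)


class TestExclusionMask:
    def test_single_peak_masks_251_samples(self):
        """135 + 365 ms at 500 Hz with inclusive integer endpoints."""
        train = RPeakTrain([5000], FS)
        mask = ecg_exclusion_mask(train, 10000)
        assert mask.n_excluded == 251

    def test_empty_train_keeps_everything(self):
        mask = ecg_exclusion_mask(RPeakTrain([], FS), 1000)
        assert mask.keep.all()

    def test_close_peaks_merge_into_one_run(self):
        train = RPeakTrain([1000, 1150], FS)  # 300 ms apart
        mask = ecg_exclusion_mask(train, 3000)
        runs = np.diff(np.flatnonzero(np.diff(mask.keep.astype(int))))
        # exactly one contiguous excluded run: two transitions in the mask
        assert np.sum(np.abs(np.diff(mask.keep.astype(int)))) == 2

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=4000), min_size=0,
                    max_size=8, unique=True))
    def test_mask_equals_interval_union_oracle(self, raw):
        """Excluded-sample count equals the measure of the window union."""
        idx = sorted(raw)
        idx = [p for i, p in enumerate(idx)
               if i == 0 or p - idx[i - 1] >= 0.2 * FS]
        train = RPeakTrain(idx, FS)
        n = 5000
        mask = ecg_exclusion_mask(train, n)
        pre, post = int(np.round(0.135 * FS)), int(np.round(0.365 * FS))
        union = set()
        for p in idx:
            union.update(range(max(0, p - pre), min(n, p + post + 1)))
        assert mask.n_excluded == len(union)
        assert np.array_equal(~mask.keep,
                              np.isin(np.arange(n), sorted(union)))


class TestRPeakDetection:
    def test_closed_loop_recovery(self, contaminated_record):
        rec, truth = contaminated_record
        det = detect_r_peaks(rec)
        true_pk = truth.r_peaks.indices
        tol = 0.020 * rec.sampling_rate
        hits = sum(np.min(np.abs(det.indices - p)) <= tol for p in true_pk)
        assert hits / len(true_pk) >= 0.95
        assert not det.low_confidence

    @pytest.mark.parametrize("hr, rr_expected", [(50.0, 1.2), (100.0, 0.6)])
    def test_recovered_rr_interval(self, hr, rr_expected):
        spec = SimulationSpec(n_cycles=30, rms_ratio=1.5, seed=21,
                              ecg=EcgSpec(heart_rate=hr, qrs_amplitude=8))
        rec, _ = simulate_emgdi(spec)
        det = detect_r_peaks(rec)
        rr = np.median(np.diff(det.indices)) / rec.sampling_rate
        assert rr == pytest.approx(rr_expected, rel=0.05)

    def test_pure_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(8)
        rec = Record(rng.standard_normal(int(30 * FS)), FS)
        det = detect_r_peaks(rec)
        assert det.low_confidence or len(det) == 0

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(Record(np.zeros(int(2 * FS)), FS))


class TestI2BSNR:
    def test_hand_computed_toy(self):
        """Amplitude 3 inside the cycle, 1 outside -> 20 log10(3) dB."""
        fs = 100.0
        x = np.ones(400)
        x[100:201] = 3.0
        series = compute_i2bsnr(Record(x, fs), [(1.0, 2.0)], epoch_length=4.0)
        assert series.values_db[0] == pytest.approx(ratio_to_db(3.0))

    def test_equal_rms_gives_zero_db(self):
        fs = 100.0
        x = np.ones(400)
        series = compute_i2bsnr(Record(x, fs), [(1.0, 2.0)], epoch_length=4.0)
        assert series.values_db[0] == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_ratio_ten_reads_twenty_db(self, clean_record_50):
        rec, truth = clean_record_50
        series = compute_i2bsnr(rec, truth.intervals())
        vals = series.values_db[np.isfinite(series.values_db)]
        assert vals.size >= 3
        assert np.all(np.abs(vals - 20.0) < 1.0)

    def test_monotone_in_rms_ratio(self):
        est = []
        for ratio in (1.2, 2.0, 5.0, 10.0):
            rec, truth = simulate_emgdi(
                SimulationSpec(n_cycles=30, rms_ratio=ratio, seed=31))
            s = compute_i2bsnr(rec, truth.intervals())
            est.append(np.nanmean(s.values_db))
        assert np.all(np.diff(est) > 0)

    def test_short_epoch_flagged_missing_and_carried_forward(self):
        fs = 100.0
        x = np.ones(800)
        x[100:201] = 3.0  # cycle only in the first epoch
        series = compute_i2bsnr(Record(x, fs), [(1.0, 2.0)], epoch_length=4.0)
        assert np.isfinite(series.values_db[0])
        assert np.isnan(series.values_db[1])
        filled = series.filled()
        assert filled[1] == filled[0]
        assert series.value_at(6.0) == pytest.approx(series.values_db[0])
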