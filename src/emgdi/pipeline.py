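"""End-to-end composition: conditioning -> ECG suppression -> envelope ->
cycle detection -> I2BSNR -> optional timing-bias correction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import ecg_removal
from .bias_correction import CorrectionModel, apply_correction
from .detect import CycleInterval, DetectorConfig, detect_cycles
from .envelopes import FSE_COMPATIBLE_SOURCES, compute_envelope
from .preprocess import (I2BSNRSeries, Record, SampleMask, bandpass,
                         compute_i2bsnr, detect_r_peaks, ecg_exclusion_mask,
                         notch_mains)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

ECG_METHODS = ("none", "wavelet", "gating", "adaptive", "adaptive_gating")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full detection pipeline.

    The entropy envelope is only valid on the raw or adaptively filtered
    signal; requesting it after gating or wavelet denoising is rejected at
    configuration time.
    """

    ecg_method: str = "adaptive"
    envelope_method: str = "fse"
    envelope_stage: str = "e3"
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    epoch_length: float = 30.0
    notch_harmonics: int = 0          # 0 disables the mains notch
    mains_freq: float = 50.0
    band: tuple[float, float] = (5.0, 200.0)

    def __post_init__(self) -> None:
        if self.ecg_method not in ECG_METHODS:
            raise ValueError(f"ecg_method must be one of {ECG_METHODS}")
        if self.envelope_method not in ("rms", "fse"):
            raise ValueError("envelope_method must be 'rms' or 'fse'")
        if self.envelope_stage not in ("e1", "e2", "e3"):
            raise ValueError("envelope_stage must be e1, e2 or e3")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        if (self.envelope_method == "fse"
                and self.ecg_method not in FSE_COMPATIBLE_SOURCES):
            raise ValueError(
                f"envelope_method='fse' is incompatible with ecg_method="
                f"{self.ecg_method!r}: gating and wavelet thresholding "
                "distort the random components the entropy envelope "
                "measures (use ecg_method 'none' or 'adaptive')")


@dataclass
class PipelineResult:
    cycles: list[CycleInterval]
    all_candidates: list[CycleInterval]
    i2bsnr: I2BSNRSeries
    envelope: object
    mask: SampleMask
    preprocessed: Record
    cleaned: Record


def run_pipeline(record: Record, config: PipelineConfig | None = None,
                 correction: Optional[CorrectionModel] = None
                 ) -> PipelineResult:
    """Run the full cycle-detection pipeline on a raw record."""
    cfg = config or PipelineConfig()
    rec = bandpass(record, *cfg.band)
    if cfg.notch_harmonics > 0:
        rec = notch_mains(rec, cfg.mains_freq, cfg.notch_harmonics)

    rpeaks = detect_r_peaks(rec)
    if rpeaks.low_confidence and cfg.ecg_method != "none":
        warnings.warn(
            "R-peak detection is low-confidence; ECG suppression "
            f"({cfg.ecg_method}) may degrade the signal")

    if cfg.ecg_method == "none":
        cleaned = rec
    elif cfg.ecg_method == "wavelet":
        cleaned = ecg_removal.wavelet_denoise(rec, rpeaks)
    elif cfg.ecg_method == "gating":
        cleaned = ecg_removal.gate(rec, rpeaks)
    elif cfg.ecg_method == "adaptive":
        cleaned = ecg_removal.adaptive_cancel(rec, rpeaks)
    else:
        cleaned = ecg_removal.adaptive_then_gate(rec, rpeaks)

    env = compute_envelope(cleaned, cfg.envelope_method, cfg.envelope_stage,
                           source_method=("none" if cfg.ecg_method == "none"
                                          else cfg.ecg_method))
    cycles, candidates = detect_cycles(env, cfg.detector)

    if len(rpeaks) and not rpeaks.low_confidence:
        mask = ecg_exclusion_mask(rpeaks, rec.n_samples)
    else:
        mask = SampleMask(np.ones(rec.n_samples, dtype=bool))
    i2bsnr = compute_i2bsnr(rec, cycles, mask, cfg.epoch_length)

    if correction is not None:
        cycles = apply_correction(cycles, i2bsnr, correction)
    return PipelineResult(cycles=cycles, all_candidates=candidates,
                          i2bsnr=i2bsnr, envelope=env, mask=mask,
                          preprocessed=rec, cleaned=cleaned)
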