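"""Signal conditioning for PPG channels.

Pipeline order: zero-phase low-pass filtering, wavelet denoising, baseline
(DC) extraction, pulsatile (AC) isolation, z-score standardization, integer
decimation, and 10-s/2-s sliding windows.  The baseline is kept in absolute
ADC counts throughout — the dual-channel DC difference is the method's key
feature, and standardizing it away would destroy exactly the information the
estimator depends on.  Standardization therefore applies to the pulsatile
path only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .signal_model import TimeSeries, ValidationError

__all__ = [
    "PreprocConfig",
    "ConditionedChannel",
    "WindowSlice",
    "lowpass_filter",
    "wavelet_denoise",
    "extract_baseline",
    "standardize",
    "downsample",
    "make_windows",
    "condition_channel",
]


@dataclass
class PreprocConfig:
    """Conditioning parameters.

    Defaults: 4th-order Butterworth low-pass at 10 Hz (pulse energy lies below
    10 Hz), Daubechies-8 wavelet at level 4 with the universal soft threshold,
    baseline band edge 0.4 Hz (below the slowest plausible heart rate of
    ~0.5 Hz), 500 Hz feature rate, and 10-s windows shifted by 2 s.
    """

    lowpass_cutoff: float = 10.0
    lowpass_order: int = 4
    wavelet_name: str = "db8"
    decomposition_level: int = 4
    threshold_rule: str = "universal_soft"
    baseline_band_edge: float = 0.4
    feature_rate: float = 500.0
    window_length: float = 10.0
    window_shift: float = 2.0

    def validate(self) -> None:
        if not (0 < self.baseline_band_edge < self.lowpass_cutoff < self.feature_rate / 2):
            raise ValidationError(
                "require 0 < baseline_band_edge < lowpass_cutoff < feature_rate/2"
            )
        if self.window_shift > self.window_length:
            raise ValidationError("window_shift must not exceed window_length")
        if self.window_shift <= 0 or self.window_length <= 0:
            raise ValidationError("window length and shift must be positive")
        if self.threshold_rule != "universal_soft":
            raise ValidationError(f"unknown threshold rule {self.threshold_rule!r}")

    @property
    def edge_margin(self) -> float:
        """One baseline period (s); session edges inside it are excluded."""
        return 1.0 / self.baseline_band_edge


@dataclass
class ConditionedChannel:
    """The four conditioned representations of one PPG channel.

    ``denoised = baseline + pulsatile`` holds pointwise by construction;
    ``standardized`` is the z-scored pulsatile component.
    """

    denoised: TimeSeries
    baseline: TimeSeries
    pulsatile: TimeSeries
    standardized: TimeSeries


@dataclass(frozen=True)
class WindowSlice:
    """One estimation window: ``[start, start + length)`` seconds."""

    start: float
    length: float

    @property
    def end(self) -> float:
        return self.start + self.length


def lowpass_filter(series: TimeSeries, cfg: PreprocConfig) -> TimeSeries:
    """Zero-phase Butterworth low-pass; same length, rate, and phase."""
    nyq = series.sampling_rate / 2.0
    if cfg.lowpass_cutoff >= nyq:
        raise ValidationError(
            f"cutoff {cfg.lowpass_cutoff:g} Hz must be below Nyquist {nyq:g} Hz"
        )
    sos = sps.butter(cfg.lowpass_order, cfg.lowpass_cutoff, fs=series.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, series.values, padtype="even")
    return series.with_values(out)


def wavelet_denoise(series: TimeSeries, cfg: PreprocConfig) -> TimeSeries:
    """Wavelet shrinkage with the universal soft threshold.

    Detail coefficients at every level are soft-thresholded at
    ``sigma * sqrt(2 ln N)`` where sigma is estimated from the median absolute
    deviation of the finest-level details (MAD / 0.6745).
    """
    x = series.values
    if x.size < 2**cfg.decomposition_level:
        raise ValidationError(
            f"series of {x.size} samples too short for level {cfg.decomposition_level}"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=cfg.decomposition_level, mode="symmetric")
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    thr = sigma * math.sqrt(2.0 * math.log(x.size))
    if thr == 0.0:  # noise-free input: nothing to shrink
        return series.with_values(x.copy())
    den = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    out = pywt.waverec(den, cfg.wavelet_name, mode="symmetric")[: x.size]
    return series.with_values(out)


def extract_baseline(series: TimeSeries, cfg: PreprocConfig) -> TimeSeries:
    """The DC component: zero-phase low-pass at the baseline band edge.

    Requires at least two baseline periods of signal so the filter has
    something to work with.
    """
    min_len = 2.0 / cfg.baseline_band_edge * series.sampling_rate
    if series.values.size < min_len:
        raise ValidationError(
            f"need >= {min_len:.0f} samples (two baseline periods) to extract a baseline"
        )
    sos = sps.butter(2, cfg.baseline_band_edge, fs=series.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, series.values, padtype="even")
    return series.with_values(out)


def standardize(series: TimeSeries) -> TimeSeries:
    """Z-score: transform to mean 0 and (population) standard deviation 1."""
    x = series.values
    if x.size < 2:
        raise ValidationError("standardization needs at least 2 samples")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValidationError("standardization undefined for zero-variance input")
    return series.with_values((x - x.mean()) / sd, units="dimensionless")


def downsample(series: TimeSeries, target_rate: float) -> TimeSeries:
    """Anti-alias filter and decimate to ``target_rate`` (integer factors only)."""
    ratio = series.sampling_rate / target_rate
    q = int(round(ratio))
    if q < 1 or not math.isclose(ratio, q, rel_tol=1e-9):
        raise ValidationError(
            f"target rate {target_rate:g} Hz does not integer-divide "
            f"{series.sampling_rate:g} Hz (resampling dialects not supported)"
        )
    if q == 1:
        return series.with_values(series.values.copy())
    out = sps.decimate(series.values, q, ftype="fir", zero_phase=True)
    return TimeSeries(out, target_rate, start_time=series.start_time, units=series.units)


def make_windows(session_duration: float, cfg: PreprocConfig) -> list[WindowSlice]:
    """All fully contained windows: starts 0, shift, 2*shift, ...

    Count equals ``floor((duration - length) / shift) + 1`` when the session is
    at least one window long, else zero.
    """
    cfg.validate()
    if session_duration + 1e-9 < cfg.window_length:
        return []
    count = int(math.floor((session_duration - cfg.window_length) / cfg.window_shift + 1e-9)) + 1
    return [WindowSlice(i * cfg.window_shift, cfg.window_length) for i in range(count)]


def condition_channel(series: TimeSeries, cfg: PreprocConfig) -> ConditionedChannel:
    """Full conditioning chain: filter -> denoise -> baseline split -> z-score."""
    cfg.validate()
    filtered = lowpass_filter(series, cfg)
    denoised = wavelet_denoise(filtered, cfg)
    baseline = extract_baseline(denoised, cfg)
    pulsatile = denoised.with_values(denoised.values - baseline.values)
    standardized = standardize(pulsatile)
    return ConditionedChannel(
        denoised=denoised,
        baseline=baseline,
        pulsatile=pulsatile,
        standardized=standardized,
    )
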