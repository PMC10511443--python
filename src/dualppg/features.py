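"""Pulse-waveform and interface-sensor feature extraction.

Per 10-s window the estimator consumes:

* the dual-channel **DC baseline difference** (dorsal minus palmar, window
  mean, in ADC counts) — the differential feature that cancels
  subject-specific optical offsets and tracks stroke volume;
* seven waveform features averaged over the window's beats, taken from the
  dorsal channel (the higher-SNR site): cardiac period (CP), systolic time
  (ST), diastolic time (DT), ST/DT, systolic/diastolic area ratio, the K
  value ``(mean - min) / (max - min)``, and the AC/DC amplitude ratio;
* contact pressures (calibrated from interface voltages) and skin
  temperatures on both sides;
* the subject's physical characteristics (heart rate, age, height, weight,
  BMI, sex).

SBP models take 11 inputs (no waveform-shape features); DBP models take all
18 — diastolic pressure is the one the reflected-wave morphology informs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ConditionedChannel, PreprocConfig, WindowSlice, condition_channel, make_windows
from .signal_model import SensorSession, SubjectProfile, TimeSeries, ValidationError

__all__ = [
    "BeatFiducials",
    "BeatFeatures",
    "WindowFeatures",
    "FeatureVector",
    "CalibrationCurve",
    "default_calibration_curve",
    "segment_beats",
    "locate_fiducials",
    "compute_beat_features",
    "compute_baseline_difference",
    "calibrate_pressure",
    "interface_window_features",
    "aggregate_window_features",
    "assemble_feature_vector",
    "extract_features_table",
    "SBP_FEATURES",
    "DBP_FEATURES",
    "WAVEFORM_FEATURES",
]

#: Ordered model-input names for the SBP target (11 features).
SBP_FEATURES = (
    "dc_difference",
    "pressure_palmar",
    "pressure_dorsal",
    "temp_palmar",
    "temp_dorsal",
    "heart_rate",
    "age",
    "height",
    "weight",
    "bmi",
    "sex",
)

#: The seven waveform-shape features appended for the DBP target.
WAVEFORM_FEATURES = (
    "cardiac_period",
    "systolic_time",
    "diastolic_time",
    "st_dt_ratio",
    "area_ratio",
    "k_value",
    "ac_dc_ratio",
)

#: Ordered model-input names for the DBP target (18 features).
DBP_FEATURES = SBP_FEATURES + WAVEFORM_FEATURES


@dataclass
class BeatFiducials:
    """Landmark times of one beat, in seconds on the session clock."""

    onset: float
    systolic_peak: float
    dicrotic_notch: float | None
    end: float

    def violations(self) -> list[str]:
        v = []
        if not (self.onset < self.systolic_peak < self.end):
            v.append("require onset < systolic_peak < end")
        if self.dicrotic_notch is not None and not (
            self.systolic_peak < self.dicrotic_notch < self.end
        ):
            v.append("require systolic_peak < dicrotic_notch < end when notch present")
        return v


@dataclass
class BeatFeatures:
    """The per-beat waveform quantities (times in s, ratios dimensionless)."""

    cp: float
    st: float
    dt: float
    st_dt_ratio: float
    area_ratio: float
    k_value: float
    ac_dc_ratio: float


@dataclass
class WindowFeatures:
    """Aggregated features of one estimation window (means over valid beats)."""

    baseline_difference: float
    cardiac_period: float
    systolic_time: float
    diastolic_time: float
    st_dt_ratio: float
    area_ratio: float
    k_value: float
    ac_dc_ratio: float
    heart_rate: float
    pressure_palmar: float
    pressure_dorsal: float
    temp_palmar: float
    temp_dorsal: float
    n_beats: int
    valid: bool


@dataclass
class FeatureVector:
    """One assembled model input: 11 entries for SBP, 18 for DBP."""

    target: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = {"SBP": len(SBP_FEATURES), "DBP": len(DBP_FEATURES)}[self.target]
        if len(self.names) != expected or self.values.size != expected:
            raise ValidationError(
                f"{self.target} feature vector must have {expected} entries"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("feature vector contains non-finite values")


# --------------------------------------------------------------------------
# Beat segmentation and fiducial delineation
# --------------------------------------------------------------------------

_MIN_PEAK_SEPARATION = 0.3  # s; physiological ceiling of 200 bpm
_FOOT_THRESHOLD = 0.05  # fraction of beat amplitude above the inter-beat minimum


def segment_beats(pulsatile: TimeSeries) -> list[tuple[float, float]]:
    """Delimit beats by successive waveform feet.

    Systolic peaks are located first (minimum separation 0.3 s, prominence a
    quarter of the robust signal amplitude); each foot is then placed on the
    rising edge where the signal first exceeds the inter-beat minimum by 5% of
    the upstroke amplitude, walking back from the peak.  Only complete beats
    (foot to next foot) are returned.  An empty list means no usable beats;
    callers flag the window invalid.
    """
    x = pulsatile.values
    fs = pulsatile.sampling_rate
    if x.size < 2.0 * fs or fs < 100.0:
        return []
    lo, hi = np.percentile(x, [2, 98])
    amp = hi - lo
    if amp <= 0:
        return []
    # the height floor rejects dicrotic (reflected-wave) peaks, which stay
    # well below the percussion peak in this waveform family
    peaks, _ = sps.find_peaks(
        x,
        distance=max(int(_MIN_PEAK_SEPARATION * fs), 1),
        prominence=0.25 * amp,
        height=lo + 0.55 * amp,
    )
    if peaks.size < 2:
        return []

    feet: list[int] = []
    for k in range(1, peaks.size):
        seg = x[peaks[k - 1] : peaks[k] + 1]
        m = seg.min()
        thr = m + _FOOT_THRESHOLD * (x[peaks[k]] - m)
        below = np.nonzero(seg <= thr)[0]
        if below.size == 0:
            continue
        feet.append(peaks[k - 1] + int(below[-1]))
    onsets = pulsatile.start_time + np.asarray(feet) / fs
    return [(float(onsets[i]), float(onsets[i + 1])) for i in range(len(onsets) - 1)]


def locate_fiducials(beat: TimeSeries) -> BeatFiducials:
    """Delineate one beat segment (from :func:`segment_beats`).

    The systolic peak is the global maximum.  The dicrotic notch is the most
    prominent local minimum between the peak and 80% of the cardiac period;
    when no local minimum exists (a merged, single-lobe pulse) the maximum of
    the second derivative in (peak + 0.1 CP, peak + 0.5 CP) stands in; if that
    fails too the notch is marked missing and the beat is excluded from the
    notch-dependent features.
    """
    x = beat.values
    fs = beat.sampling_rate
    t0 = beat.start_time
    cp = x.size / fs
    ipk = int(np.argmax(x))
    peak_t = t0 + ipk / fs

    hi = min(int(0.8 * cp * fs), x.size - 1)
    notch_t: float | None = None
    if hi - ipk > 2:
        seg = x[ipk : hi + 1]
        minima, props = sps.find_peaks(-seg, prominence=0.0)
        if minima.size:
            best = minima[int(np.argmax(props["prominences"]))]
            if 0 < best < seg.size - 1:
                notch_t = t0 + (ipk + best) / fs
    if notch_t is None:
        # inflection fallback: strongest upward curvature after the peak
        lo2 = ipk + max(int(0.1 * cp * fs), 1)
        hi2 = min(ipk + int(0.5 * cp * fs), x.size - 1)
        if hi2 - lo2 > 4:
            d2 = np.gradient(np.gradient(x))
            j = lo2 + int(np.argmax(d2[lo2 : hi2 + 1]))
            if ipk < j < x.size - 1:
                notch_t = t0 + j / fs
    return BeatFiducials(onset=t0, systolic_peak=peak_t, dicrotic_notch=notch_t, end=t0 + cp)


def compute_beat_features(
    beat: TimeSeries, fiducials: BeatFiducials, baseline: TimeSeries
) -> BeatFeatures:
    """The seven per-beat quantities.

    CP = end − onset, ST = notch − onset, DT = end − notch (so ST + DT = CP by
    construction); K = (mean − min)/(max − min) of the beat; areas are measured
    above the beat minimum by the trapezoid rule and split at the notch;
    AC/DC = peak-to-peak pulsatile amplitude over the mean baseline level of
    the beat.
    """
    if fiducials.dicrotic_notch is None:
        raise ValidationError("beat has no dicrotic notch; notch-dependent features undefined")
    if fiducials.violations():
        raise ValidationError("; ".join(fiducials.violations()))
    x = beat.values
    fs = beat.sampling_rate
    xmin, xmax = float(x.min()), float(x.max())
    if xmax <= xmin:
        raise ValidationError("degenerate beat: zero amplitude")

    cp = fiducials.end - fiducials.onset
    st = fiducials.dicrotic_notch - fiducials.onset
    dt = cp - st

    k_value = (float(x.mean()) - xmin) / (xmax - xmin)

    inotch = int(round((fiducials.dicrotic_notch - beat.start_time) * fs))
    inotch = min(max(inotch, 1), x.size - 2)
    rel = x - xmin
    area_sys = float(np.trapezoid(rel[: inotch + 1], dx=1.0 / fs))
    area_dia = float(np.trapezoid(rel[inotch:], dx=1.0 / fs))
    if area_dia <= 0:
        raise ValidationError("degenerate beat: zero diastolic area")

    base = baseline.slice(fiducials.onset, fiducials.end).values
    dc = float(base.mean())
    if dc <= 0:
        raise ValidationError("nonpositive baseline mean; AC/DC ratio undefined")

    return BeatFeatures(
        cp=cp,
        st=st,
        dt=dt,
        st_dt_ratio=st / dt,
        area_ratio=area_sys / area_dia,
        k_value=k_value,
        ac_dc_ratio=(xmax - xmin) / dc,
    )


# --------------------------------------------------------------------------
# Dual-channel baseline difference and interface-sensor features
# --------------------------------------------------------------------------

def compute_baseline_difference(
    baseline_palmar: TimeSeries, baseline_dorsal: TimeSeries, window: WindowSlice
) -> float:
    """Window-mean dorsal-minus-palmar DC difference, in ADC counts.

    Invariant under any common additive transform of both channels — the
    subject's optical offset and common-mode drift cancel exactly.
    """
    bd = baseline_dorsal.slice(window.start, window.end).values
    bp = baseline_palmar.slice(window.start, window.end).values
    n = min(bd.size, bp.size)
    return float(bd[:n].mean() - bp[:n].mean())


@dataclass
class CalibrationCurve:
    """Monotone voltage-to-pressure calibration anchors for an interface sensor."""

    voltages: np.ndarray  # V, strictly increasing
    pressures: np.ndarray  # Pa, strictly increasing

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=np.float64)
        self.pressures = np.asarray(self.pressures, dtype=np.float64)
        if self.voltages.size != self.pressures.size or self.voltages.size < 2:
            raise ValidationError("calibration needs >= 2 (voltage, pressure) anchors")
        if not (np.all(np.diff(self.voltages) > 0) and np.all(np.diff(self.pressures) > 0)):
            raise ValidationError("calibration anchors must be strictly increasing in both coordinates")


def default_calibration_curve(
    v_sat: float = 1.8, p0: float = 1500.0, p_max: float = 4000.0, step: float = 250.0
) -> CalibrationCurve:
    """Anchors of the saturating response ``V = v_sat (1 - exp(-P/p0))``.

    Matches the synthetic interface sensor; real-device curves are supplied
    through configuration.
    """
    p = np.arange(0.0, p_max + step / 2, step)
    v = v_sat * (1.0 - np.exp(-p / p0))
    return CalibrationCurve(v, p)


def calibrate_pressure(voltage: float | np.ndarray, curve: CalibrationCurve) -> float | np.ndarray:
    """Monotone piecewise-linear interpolation of the calibration anchors.

    Voltages outside the anchored range are clamped with a warning.
    """
    v = np.asarray(voltage, dtype=np.float64)
    if np.any(v < curve.voltages[0] - 1e-12) or np.any(v > curve.voltages[-1] + 1e-12):
        warnings.warn("voltage outside calibration range; clamping", stacklevel=2)
    out = np.interp(v, curve.voltages, curve.pressures)
    return float(out) if np.isscalar(voltage) or np.ndim(voltage) == 0 else out


def interface_window_features(
    session: SensorSession, window: WindowSlice, curve: CalibrationCurve
) -> tuple[float, float, float, float]:
    """(P_palmar, P_dorsal, T_palmar, T_dorsal): window means, Pa and deg C."""
    vp = session.iface_palmar_v.slice(window.start, window.end).values.mean()
    vd = session.iface_dorsal_v.slice(window.start, window.end).values.mean()
    tp = session.temp_palmar.slice(window.start, window.end).values.mean()
    td = session.temp_dorsal.slice(window.start, window.end).values.mean()
    return (
        float(calibrate_pressure(float(vp), curve)),
        float(calibrate_pressure(float(vd), curve)),
        float(tp),
        float(td),
    )


# --------------------------------------------------------------------------
# Window aggregation and model-input assembly
# --------------------------------------------------------------------------

@dataclass
class _SessionBeat:
    """One delineated dorsal beat with its features (None when rejected)."""

    onset: float
    end: float
    fiducials: BeatFiducials
    features: BeatFeatures | None


def extract_session_beats(
    cond_dorsal: ConditionedChannel,
) -> list[_SessionBeat]:
    """Segment and delineate every dorsal beat of a conditioned session once.

    Windows then select the beats they fully contain, so beat detection cost
    is paid per session, not per overlapping window.
    """
    beats: list[_SessionBeat] = []
    for onset, end in segment_beats(cond_dorsal.pulsatile):
        seg = cond_dorsal.pulsatile.slice(onset, end)
        fid = locate_fiducials(seg)
        feats: BeatFeatures | None = None
        if fid.dicrotic_notch is not None and not fid.violations():
            try:
                feats = compute_beat_features(seg, fid, cond_dorsal.baseline)
            except ValidationError:
                feats = None
        beats.append(_SessionBeat(onset, end, fid, feats))
    return beats


def aggregate_window_features(
    session: SensorSession,
    cond_palmar: ConditionedChannel,
    cond_dorsal: ConditionedChannel,
    window: WindowSlice,
    curve: CalibrationCurve,
    min_beats: int = 5,
    beats: Sequence[_SessionBeat] | None = None,
) -> WindowFeatures:
    """Aggregate one window: beat-feature means, DC difference, interface means.

    A window is valid only if it contains at least ``min_beats`` accepted
    beats (beats lying entirely within the window with a located notch).
    Invalid windows are flagged, never raised.
    """
    if beats is None:
        beats = extract_session_beats(cond_dorsal)
    inside = [
        b
        for b in beats
        if b.onset >= window.start - 1e-9 and b.end <= window.end + 1e-9 and b.features is not None
    ]
    n = len(inside)
    ddc = compute_baseline_difference(cond_palmar.baseline, cond_dorsal.baseline, window)
    pp, pdors, tp, td = interface_window_features(session, window, curve)
    if n < min_beats:
        nan = float("nan")
        return WindowFeatures(
            baseline_difference=ddc,
            cardiac_period=nan, systolic_time=nan, diastolic_time=nan,
            st_dt_ratio=nan, area_ratio=nan, k_value=nan, ac_dc_ratio=nan,
            heart_rate=nan,
            pressure_palmar=pp, pressure_dorsal=pdors, temp_palmar=tp, temp_dorsal=td,
            n_beats=n, valid=False,
        )
    mean = lambda attr: float(np.mean([getattr(b.features, attr) for b in inside]))
    cp = mean("cp")
    return WindowFeatures(
        baseline_difference=ddc,
        cardiac_period=cp,
        systolic_time=mean("st"),
        diastolic_time=mean("dt"),
        st_dt_ratio=mean("st_dt_ratio"),
        area_ratio=mean("area_ratio"),
        k_value=mean("k_value"),
        ac_dc_ratio=mean("ac_dc_ratio"),
        heart_rate=60.0 / cp,
        pressure_palmar=pp,
        pressure_dorsal=pdors,
        temp_palmar=tp,
        temp_dorsal=td,
        n_beats=n,
        valid=True,
    )


def assemble_feature_vector(
    wf: WindowFeatures, profile: SubjectProfile, target: str
) -> FeatureVector:
    """Build the ordered model input for one window: 11 (SBP) or 18 (DBP) entries."""
    if target not in ("SBP", "DBP"):
        raise ValidationError(f"target must be 'SBP' or 'DBP', got {target!r}")
    if not wf.valid:
        raise ValidationError("window is flagged invalid; refusing to assemble features")
    for fname in ("age", "height", "weight", "bmi", "sex", "heart_rate"):
        val = getattr(profile, fname)
        if val is None or (isinstance(val, float) and not math.isfinite(val)):
            raise ValidationError(f"profile field {fname!r} is missing")
    base = {
        "dc_difference": wf.baseline_difference,
        "pressure_palmar": wf.pressure_palmar,
        "pressure_dorsal": wf.pressure_dorsal,
        "temp_palmar": wf.temp_palmar,
        "temp_dorsal": wf.temp_dorsal,
        "heart_rate": wf.heart_rate,
        "age": profile.age,
        "height": profile.height,
        "weight": profile.weight,
        "bmi": profile.bmi,
        "sex": float(profile.sex),
        "cardiac_period": wf.cardiac_period,
        "systolic_time": wf.systolic_time,
        "diastolic_time": wf.diastolic_time,
        "st_dt_ratio": wf.st_dt_ratio,
        "area_ratio": wf.area_ratio,
        "k_value": wf.k_value,
        "ac_dc_ratio": wf.ac_dc_ratio,
    }
    names = SBP_FEATURES if target == "SBP" else DBP_FEATURES
    return FeatureVector(target=target, names=names, values=np.array([base[n] for n in names]))


def extract_features_table(
    session: SensorSession,
    preproc_cfg: PreprocConfig | None = None,
    curve: CalibrationCurve | None = None,
    min_beats: int = 5,
) -> pd.DataFrame:
    """All window features of one session as a tidy table.

    One row per window with the 18 named features, the nearest-in-time cuff
    reference (aligned to the window end, the estimate time), beat count, and
    validity flag.  Windows overlapping the first or last baseline period of
    the session are excluded (filter edge effects).
    """
    cfg = preproc_cfg or PreprocConfig()
    cfg.validate()
    curve = curve or default_calibration_curve()
    cond_p = condition_channel(session.ppg_palmar, cfg)
    cond_d = condition_channel(session.ppg_dorsal, cfg)
    beats = extract_session_beats(cond_d)

    duration = session.duration
    margin = cfg.edge_margin
    windows = [
        w
        for w in make_windows(duration, cfg)
        if w.start >= margin - 1e-9 and w.end <= duration - margin + 1e-9
    ]
    ref_times = np.array([r.time for r in session.references])
    rows = []
    for w in windows:
        wf = aggregate_window_features(
            session, cond_p, cond_d, w, curve, min_beats=min_beats, beats=beats
        )
        row: dict[str, object] = {
            "session_id": session.session_id,
            "subject_id": session.profile.subject_id,
            "window_start_s": w.start,
        }
        for name in DBP_FEATURES:
            if name in ("age", "height", "weight", "bmi"):
                row[name] = getattr(session.profile, name)
            elif name == "sex":
                row[name] = float(session.profile.sex)
            else:
                row[name] = getattr(
                    wf, "baseline_difference" if name == "dc_difference" else name
                )
        if ref_times.size:
            j = int(np.argmin(np.abs(ref_times - w.end)))
            row["sbp_ref"] = session.references[j].sbp
            row["dbp_ref"] = session.references[j].dbp
        else:
            row["sbp_ref"] = row["dbp_ref"] = float("nan")
        row["n_beats"] = wf.n_beats
        row["valid"] = wf.valid
        rows.append(row)
    return pd.DataFrame(rows)
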