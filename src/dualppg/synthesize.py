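"""Synthetic cohorts of dual-PPG wearing sessions with known hemodynamics.

Real recordings of this kind (dual-wrist PPG plus interface-sensor pressure and
skin temperature, against cuff references) are not publicly deposited, so this
module generates sessions whose latent hemodynamic state — stroke volume,
peripheral resistance, heart rate, contact pressure, skin temperature — is
known exactly, together with ground-truth beat fiducials and blood pressure.
Every downstream stage (conditioning, feature extraction, fusion, evaluation)
is tested against these oracles.

The optical model per PPG channel is::

    signal = alpha_subj + beta_ch * SV + gamma * P_contact_ch      (DC level)
           + drift_amplitude * sin(2*pi*drift_freq*t + phase)      (respiration)
           + amp_ch * g_subj * (pulse template - template mean)    (AC pulses)
           + white noise

The subject optical offset ``alpha_subj`` and the respiratory drift are common
to both channels, so the dorsal-minus-palmar DC difference cancels them and
retains ``(beta_dorsal - beta_palmar) * SV`` plus a small contact-pressure
term — the differential-sensing premise the estimation method rests on.

Blood pressure follows a linear forward model of the latent state (documented
in the package methods note); its coefficients are simulator choices exposed in
:class:`SimulationConfig`, chosen to encode the qualitative physiology (SBP
rises with stroke volume and heart rate and falls with skin temperature; DBP
rises with peripheral resistance) with recoverable structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signal_model import (
    Dataset,
    ReferenceReading,
    SensorSession,
    SubjectProfile,
    TimeSeries,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "LatentState",
    "BeatTruth",
    "GroundTruth",
    "sample_subject",
    "synthesize_beat_template",
    "synthesize_session",
    "generate_cohort",
    "default_bp_coefficients",
]


def default_bp_coefficients() -> dict[str, float]:
    """Forward-model coefficients mapping latent state to true SBP/DBP (mmHg).

    SBP = sbp_intercept + sbp_sv*SV + sbp_hr*HR + sbp_temp*(Tmean-33)
          + sbp_pressure*(P_palmar+P_dorsal)
    DBP = dbp_intercept + dbp_r*R + dbp_hr*HR + dbp_temp*(Tmean-33)
    """
    return {
        "sbp_intercept": 40.0,
        "sbp_sv": 0.8,
        "sbp_hr": 0.2,
        "sbp_temp": -1.5,
        "sbp_pressure": 0.002,
        "dbp_intercept": 20.0,
        "dbp_r": 40.0,
        "dbp_hr": 0.15,
        "dbp_temp": -1.0,
    }


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    The defaults are the package's reference study conditions: 18 subjects with
    4 sessions each of 120 s, DC level ~5e4 ADC counts dwarfing the ~500-count
    AC pulses, sensor noise at ~20 dB SNR relative to the AC component, 0.25 Hz
    respiratory drift, and 2 mmHg unexplained blood-pressure noise.
    """

    n_subjects: int = 18
    sessions_per_subject: int = 4
    session_duration: float = 120.0
    seed: int = 0

    # optical model
    gain_model: str = "additive_offset"  # or "multiplicative"
    alpha_mean: float = 50_000.0  # mean subject optical DC offset, ADC counts
    alpha_sd: float = 8_000.0  # between-subject spread of the offset
    beta_palmar: float = 2.0  # ADC counts per mL of stroke volume
    beta_dorsal: float = 3.5
    gamma_pressure: float = 0.005  # ADC counts per Pa of contact pressure
    amp_palmar: float = 400.0  # AC pulse amplitude scale, ADC counts
    amp_dorsal: float = 600.0
    ac_gain_sd: float = 0.10  # lognormal sd of per-subject AC gain
    noise_sd_ppg: float = 15.0  # white sensor noise, ADC counts (~20 dB SNR)
    drift_amplitude: float = 150.0  # respiratory baseline drift, ADC counts
    drift_freq: float = 0.25  # Hz

    # hemodynamics
    sv_mean: float = 70.0  # mL; between-subject sd below
    sv_between_sd: float = 10.0
    sv_within_sd: float = 5.0  # session-to-session within a subject
    r_mean: float = 1.0  # peripheral-resistance index
    r_between_sd: float = 0.15
    r_within_sd: float = 0.05
    bp_coefficients: dict[str, float] = field(default_factory=default_bp_coefficients)
    bp_noise_sd: float = 2.0  # mmHg, per reference reading
    # optional stressor: a per-subject BP residual no measured feature explains;
    # zero under the reference conditions so the forward model stays fully
    # feature-recoverable
    subject_bp_offset_sd: float = 0.0
    reference_interval: float = 2.0  # s between cuff reference readings

    # interface sensors
    pressure_low: float = 500.0  # Pa, wearing-pressure range
    pressure_high: float = 3000.0
    pressure_dorsal_sd: float = 200.0  # dorsal offset around palmar (same strap)
    v_sat: float = 1.8  # interface-sensor saturation voltage, V
    p0: float = 1500.0  # pressure scale of the saturating response, Pa
    iface_noise_sd: float = 0.002  # V
    temp_mean: float = 33.0  # deg C
    temp_sd: float = 1.0
    temp_noise_sd: float = 0.02

    ppg_rate: float = 1000.0
    iface_rate: float = 125.0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.sessions_per_subject < 1:
            raise ValidationError("subject and session counts must be >= 1")
        if self.session_duration <= 0:
            raise ValidationError("session_duration must be positive")
        for name in ("noise_sd_ppg", "bp_noise_sd", "alpha_sd", "ac_gain_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 < self.drift_freq < 1):
            raise ValidationError("drift_freq must lie in (0, 1) Hz")
        if self.gain_model not in ("additive_offset", "multiplicative"):
            raise ValidationError(f"unknown gain_model {self.gain_model!r}")


@dataclass
class LatentState:
    """Latent hemodynamic state of one session (the simulation's hidden truth)."""

    stroke_volume: float  # mL
    peripheral_resistance: float  # dimensionless index
    heart_rate: float  # bpm
    contact_pressure_palmar: float  # Pa
    contact_pressure_dorsal: float  # Pa
    skin_temp_palmar: float  # deg C
    skin_temp_dorsal: float  # deg C
    subject_optical_offset: float  # ADC counts (alpha_subj)
    subject_ac_gain: float = 1.0  # per-subject pulse-amplitude multiplier
    sbp_offset: float = 0.0  # per-subject unmeasured BP residual, mmHg
    dbp_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.stroke_volume > 0 and self.peripheral_resistance > 0):
            raise ValidationError("stroke volume and peripheral resistance must be > 0")
        if not (30.0 <= self.heart_rate <= 200.0):
            raise ValidationError("heart_rate must lie in [30, 200] bpm")


@dataclass
class BeatTruth:
    """True fiducial times (s, session clock) of one simulated beat."""

    onset: float
    systolic_peak: float
    dicrotic_notch: float
    end: float


@dataclass
class GroundTruth:
    """Per-session oracle: fiducials, true BP trajectory, and latent state."""

    session_id: str
    beats: list[BeatTruth]
    reference_times: np.ndarray  # s
    sbp: np.ndarray  # mmHg, one per reference time
    dbp: np.ndarray
    latent: LatentState
    dc_palmar: float  # constructed noise/drift-free DC level, ADC counts
    dc_dorsal: float
    drift_phase: float  # radians, common to both PPG channels

    def true_baseline(self, channel: str, t: np.ndarray, config: SimulationConfig) -> np.ndarray:
        """Noise-free DC + respiratory-drift trajectory of a PPG channel."""
        dc = {"ppg_palmar": self.dc_palmar, "ppg_dorsal": self.dc_dorsal}[channel]
        return dc + config.drift_amplitude * np.sin(
            2 * np.pi * config.drift_freq * np.asarray(t) + self.drift_phase
        )


def sample_subject(rng: np.random.Generator, index: int = 0) -> SubjectProfile:
    """Draw one subject profile from the cohort's demographic distribution.

    Ages ~ N(25, 3) clipped to [18, 60], heights ~ N(170, 8) cm, BMI ~
    N(21.1, 2.6) (weight derived), sex ~ Bernoulli(0.7 male), resting heart
    rate ~ N(70, 7) bpm — a young healthy cohort.
    """
    age = float(np.clip(rng.normal(25.0, 3.0), 18.0, 60.0))
    height = float(np.clip(rng.normal(170.0, 8.0), 145.0, 200.0))
    bmi_target = float(np.clip(rng.normal(21.1, 2.6), 15.0, 35.0))
    weight = bmi_target * (height / 100.0) ** 2
    sex = int(rng.random() < 0.7)
    heart_rate = float(np.clip(rng.normal(70.0, 7.0), 50.0, 110.0))
    height_r, weight_r = round(height, 1), round(weight, 2)
    return SubjectProfile(
        subject_id=f"S{index:03d}",
        age=round(age, 1),
        height=height_r,
        weight=weight_r,
        sex=sex,
        bmi=round(weight_r / (height_r / 100.0) ** 2, 3),
        heart_rate=round(heart_rate, 1),
    )


# --------------------------------------------------------------------------
# Pulse morphology
# --------------------------------------------------------------------------

# Template geometry, as fractions of the beat period: a narrow percussion lobe
# early in systole and a broader dicrotic (reflected) lobe whose amplitude and
# delay grow with peripheral resistance.  Typical systolic upstroke occupies
# ~10-15% of the cycle.
_PERC_CENTER = 0.12
_PERC_WIDTH = 0.045
_DICR_CENTER_BASE = 0.45
_DICR_CENTER_R = 0.05
_DICR_AMP_BASE = 0.25
_DICR_AMP_R = 0.20


def _template_params(latent: LatentState, beat_period: float) -> tuple[float, float, float, float, float]:
    r = latent.peripheral_resistance
    c1 = _PERC_CENTER * beat_period
    s1 = _PERC_WIDTH * beat_period
    c2 = (_DICR_CENTER_BASE + _DICR_CENTER_R * r) * beat_period
    s2 = 0.11 * beat_period
    a2 = _DICR_AMP_BASE + _DICR_AMP_R * r
    return c1, s1, c2, s2, a2


def _template_values(tau: np.ndarray, latent: LatentState, beat_period: float) -> np.ndarray:
    c1, s1, c2, s2, a2 = _template_params(latent, beat_period)
    return np.exp(-0.5 * ((tau - c1) / s1) ** 2) + a2 * np.exp(-0.5 * ((tau - c2) / s2) ** 2)


def synthesize_beat_template(
    latent: LatentState, beat_period: float, fs: float
) -> tuple[np.ndarray, BeatTruth]:
    """One noise-free pulse beat plus its exact landmark times.

    The pulse is the sum of two positive Gaussian lobes (percussion +
    dicrotic); the dicrotic lobe's relative amplitude and delay increase with
    peripheral resistance.  Landmarks are located by dense scan of the
    analytic template: onset 0, systolic peak = mode of the combined wave,
    dicrotic notch = the local minimum between the lobes, end = beat period.

    Raises a domain error for beat periods outside [0.3, 2] s.
    """
    if not (0.3 <= beat_period <= 2.0):
        raise ValidationError(f"beat_period {beat_period:g} s outside [0.3, 2] s")
    n = int(round(beat_period * fs))
    tau = np.arange(n) / fs
    wave = _template_values(tau, latent, beat_period)

    # landmark scan at 0.1 ms resolution, independent of the requested fs
    fine = np.arange(0.0, beat_period, 1e-4)
    vals = _template_values(fine, latent, beat_period)
    c1, _, c2, _, _ = _template_params(latent, beat_period)
    peak_t = float(fine[np.argmax(vals)])
    between = (fine > c1) & (fine < c2)
    notch_t = float(fine[between][np.argmin(vals[between])])
    truth = BeatTruth(onset=0.0, systolic_peak=peak_t, dicrotic_notch=notch_t, end=beat_period)
    return wave, truth


# --------------------------------------------------------------------------
# Session and cohort assembly
# --------------------------------------------------------------------------

@dataclass
class _SubjectEffects:
    """Subject-level latent effects shared by all of a subject's sessions."""

    alpha: float
    mult_gain: float
    sv_mean: float
    r_mean: float
    ac_gain: float
    sbp_offset: float
    dbp_offset: float


def _sample_subject_effects(cfg: SimulationConfig, rng: np.random.Generator) -> _SubjectEffects:
    return _SubjectEffects(
        alpha=rng.normal(cfg.alpha_mean, cfg.alpha_sd),
        mult_gain=float(np.exp(rng.normal(0.0, 0.15))),
        sv_mean=rng.normal(cfg.sv_mean, cfg.sv_between_sd),
        r_mean=rng.normal(cfg.r_mean, cfg.r_between_sd),
        ac_gain=float(np.exp(rng.normal(0.0, cfg.ac_gain_sd))),
        sbp_offset=rng.normal(0.0, cfg.subject_bp_offset_sd),
        dbp_offset=rng.normal(0.0, cfg.subject_bp_offset_sd),
    )


def _sample_latent(
    profile: SubjectProfile,
    eff: _SubjectEffects,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> LatentState:
    sv = float(np.clip(rng.normal(eff.sv_mean, cfg.sv_within_sd), 20.0, 150.0))
    r = float(np.clip(rng.normal(eff.r_mean, cfg.r_within_sd), 0.2, 3.0))
    hr = float(np.clip(rng.normal(profile.heart_rate, 4.0), 45.0, 140.0))
    p_palmar = float(rng.uniform(cfg.pressure_low, cfg.pressure_high))
    p_dorsal = float(
        np.clip(p_palmar + rng.normal(0.0, cfg.pressure_dorsal_sd), 100.0, 3950.0)
    )
    return LatentState(
        stroke_volume=sv,
        peripheral_resistance=r,
        heart_rate=hr,
        contact_pressure_palmar=p_palmar,
        contact_pressure_dorsal=p_dorsal,
        skin_temp_palmar=float(rng.normal(cfg.temp_mean, cfg.temp_sd)),
        skin_temp_dorsal=float(rng.normal(cfg.temp_mean, cfg.temp_sd)),
        subject_optical_offset=eff.alpha,
        subject_ac_gain=eff.ac_gain,
        sbp_offset=eff.sbp_offset,
        dbp_offset=eff.dbp_offset,
    )


def true_bp(latent: LatentState, coeffs: dict[str, float]) -> tuple[float, float]:
    """Noise-free SBP/DBP (mmHg) of a latent state under the forward model."""
    tmean = 0.5 * (latent.skin_temp_palmar + latent.skin_temp_dorsal)
    sbp = (
        coeffs["sbp_intercept"]
        + coeffs["sbp_sv"] * latent.stroke_volume
        + coeffs["sbp_hr"] * latent.heart_rate
        + coeffs["sbp_temp"] * (tmean - 33.0)
        + coeffs["sbp_pressure"]
        * (latent.contact_pressure_palmar + latent.contact_pressure_dorsal)
        + latent.sbp_offset
    )
    dbp = (
        coeffs["dbp_intercept"]
        + coeffs["dbp_r"] * latent.peripheral_resistance
        + coeffs["dbp_hr"] * latent.heart_rate
        + coeffs["dbp_temp"] * (tmean - 33.0)
        + latent.dbp_offset
    )
    return float(sbp), float(dbp)


def dc_levels(latent: LatentState, cfg: SimulationConfig) -> tuple[float, float]:
    """Constructed noise/drift-free DC level of each PPG channel (palmar, dorsal)."""
    dc_p = (
        latent.subject_optical_offset
        + cfg.beta_palmar * latent.stroke_volume
        + cfg.gamma_pressure * latent.contact_pressure_palmar
    )
    dc_d = (
        latent.subject_optical_offset
        + cfg.beta_dorsal * latent.stroke_volume
        + cfg.gamma_pressure * latent.contact_pressure_dorsal
    )
    return float(dc_p), float(dc_d)


def synthesize_session(
    profile: SubjectProfile,
    latent: LatentState,
    config: SimulationConfig,
    rng: np.random.Generator,
    session_id: str | None = None,
    mult_gain: float = 1.0,
) -> tuple[SensorSession, GroundTruth]:
    """Render one session's six channels plus its ground truth.

    The beat period is constant within a session (60/HR seconds), so a 60 s
    session at 60 bpm contains exactly 60 true beats.  Cuff reference readings
    are emitted every ``reference_interval`` seconds at the estimate cadence;
    each reading is the forward-model BP plus N(0, bp_noise_sd) noise.
    """
    config.validate()
    fs = config.ppg_rate
    dur = config.session_duration
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    period = 60.0 / latent.heart_rate
    _, beat_truth = synthesize_beat_template(latent, period, fs)
    n_beats = int(math.floor(dur / period + 1e-9))
    beats = [
        BeatTruth(
            onset=i * period,
            systolic_peak=i * period + beat_truth.systolic_peak,
            dicrotic_notch=i * period + beat_truth.dicrotic_notch,
            end=(i + 1) * period,
        )
        for i in range(n_beats)
    ]

    # periodic pulse train, mean-centred so the DC level stays identifiable
    pulse = _template_values(np.mod(t, period), latent, period)
    pulse -= pulse.mean()

    dc_p, dc_d = dc_levels(latent, config)
    drift_phase = float(rng.uniform(0.0, 2 * np.pi))
    drift = config.drift_amplitude * np.sin(2 * np.pi * config.drift_freq * t + drift_phase)

    def ppg_channel(dc: float, amp: float) -> np.ndarray:
        x = dc + drift + amp * latent.subject_ac_gain * pulse
        if config.gain_model == "multiplicative":
            x = x * mult_gain
        return x + rng.normal(0.0, config.noise_sd_ppg, size=n)

    ppg_palmar = ppg_channel(dc_p, config.amp_palmar)
    ppg_dorsal = ppg_channel(dc_d, config.amp_dorsal)

    n_if = int(round(dur * config.iface_rate))

    def iface_voltage(p: float) -> np.ndarray:
        v = config.v_sat * (1.0 - math.exp(-p / config.p0))
        return v + rng.normal(0.0, config.iface_noise_sd, size=n_if)

    def temp_channel(temp: float) -> np.ndarray:
        return temp + rng.normal(0.0, config.temp_noise_sd, size=n_if)

    ref_times = np.arange(config.reference_interval, dur + 1e-9, config.reference_interval)
    sbp0, dbp0 = true_bp(latent, config.bp_coefficients)
    sbp = sbp0 + rng.normal(0.0, config.bp_noise_sd, size=ref_times.size)
    dbp = dbp0 + rng.normal(0.0, config.bp_noise_sd, size=ref_times.size)
    dbp = np.minimum(dbp, sbp - 10.0)  # keep sbp > dbp even in the noise tails

    sid = session_id or f"{profile.subject_id}-r00"
    session = SensorSession(
        session_id=sid,
        profile=profile,
        ppg_palmar=TimeSeries(ppg_palmar, fs, units="adc_counts"),
        ppg_dorsal=TimeSeries(ppg_dorsal, fs, units="adc_counts"),
        iface_palmar_v=TimeSeries(
            iface_voltage(latent.contact_pressure_palmar), config.iface_rate, units="volts"
        ),
        iface_dorsal_v=TimeSeries(
            iface_voltage(latent.contact_pressure_dorsal), config.iface_rate, units="volts"
        ),
        temp_palmar=TimeSeries(
            temp_channel(latent.skin_temp_palmar), config.iface_rate, units="celsius"
        ),
        temp_dorsal=TimeSeries(
            temp_channel(latent.skin_temp_dorsal), config.iface_rate, units="celsius"
        ),
        references=[
            ReferenceReading(float(ti), float(si), float(di))
            for ti, si, di in zip(ref_times, sbp, dbp)
        ],
    )
    truth = GroundTruth(
        session_id=sid,
        beats=beats,
        reference_times=ref_times,
        sbp=np.asarray(sbp),
        dbp=np.asarray(dbp),
        latent=latent,
        dc_palmar=dc_p,
        dc_dorsal=dc_d,
        drift_phase=drift_phase,
    )
    return session, truth


def generate_cohort(config: SimulationConfig) -> tuple[Dataset, list[GroundTruth]]:
    """Generate the full cohort: n_subjects x sessions_per_subject sessions.

    Fully reproducible from ``config.seed``: every stream of randomness is
    spawned from one seed sequence, so the same config yields bit-identical
    cohorts.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(config.n_subjects)
    sessions: list[SensorSession] = []
    truths: list[GroundTruth] = []
    for i, seq in enumerate(subj_seqs):
        rng = np.random.Generator(np.random.PCG64(seq))
        profile = sample_subject(rng, index=i)
        eff = _sample_subject_effects(config, rng)
        for j in range(config.sessions_per_subject):
            latent = _sample_latent(profile, eff, config, rng)
            session, truth = synthesize_session(
                profile,
                latent,
                config,
                rng,
                session_id=f"{profile.subject_id}-r{j:02d}",
                mult_gain=eff.mult_gain,
            )
            sessions.append(session)
            truths.append(truth)
    return Dataset(sessions), truths
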