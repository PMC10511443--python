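"""Core domain types and session I/O for dual-wrist PPG blood-pressure data.

A wearing session bundles four kinds of uniformly sampled channels — palmar and
dorsal photoplethysmograms (PPG, 1 kHz), interface-sensor contact voltages and
skin temperatures (125 Hz) — together with the subject's physical
characteristics and cuff-based reference blood-pressure readings.  These types
are the substrate every later stage (conditioning, feature extraction, model
fusion, evaluation) operates on.

Sessions serialize to a plain directory: ``metadata.json`` plus one
``<channel>.csv`` file (``time_s,value``) per channel; a zip archive of such a
directory is accepted transparently on read.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "TimeSeries",
    "SubjectProfile",
    "ReferenceReading",
    "SensorSession",
    "Dataset",
    "CHANNEL_NAMES",
    "read_session",
    "write_session",
    "validate_session",
]

#: Channel units recognised throughout the package.
UNITS = ("adc_counts", "volts", "celsius", "pascal", "mmhg", "dimensionless")

#: Canonical channel names of a session, in serialization order.
CHANNEL_NAMES = (
    "ppg_palmar",
    "ppg_dorsal",
    "iface_palmar_v",
    "iface_dorsal_v",
    "temp_palmar",
    "temp_dorsal",
)

#: Default sampling rates (Hz) of the wearable's channels.
PPG_RATE = 1000.0
IFACE_RATE = 125.0


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class TimeSeries:
    """A uniformly sampled sensor channel.

    Parameters
    ----------
    values : array-like of float
        Channel samples, in ``units``.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    start_time : float
        Time of the first sample, seconds from session start.
    units : str
        One of :data:`UNITS`.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("TimeSeries requires a 1-D array with >= 1 sample")
        if not np.isfinite(self.values).all():
            raise ValidationError("TimeSeries values must all be finite")
        if not (self.sampling_rate > 0):
            raise ValidationError("sampling_rate must be > 0")
        if self.units not in UNITS:
            raise ValidationError(f"unknown units {self.units!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Length of the channel in seconds (``n / sampling_rate``)."""
        return self.values.size / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Sample times in seconds from session start."""
        return self.start_time + np.arange(self.values.size) / self.sampling_rate

    def index_range(self, t0: float, t1: float) -> tuple[int, int]:
        """Half-open sample index range covering session times ``[t0, t1)``."""
        fs = self.sampling_rate
        i0 = int(math.ceil((t0 - self.start_time) * fs - 1e-9))
        i1 = int(math.ceil((t1 - self.start_time) * fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.values.size)
        return i0, i1

    def slice(self, t0: float, t1: float) -> "TimeSeries":
        """Sub-series covering ``[t0, t1)``; raises if the span is uncovered."""
        if t0 < self.start_time - 0.5 / self.sampling_rate or t1 > self.end_time + 0.5 / self.sampling_rate:
            raise ValidationError(
                f"requested span [{t0}, {t1}) s not covered by channel "
                f"[{self.start_time}, {self.end_time}) s"
            )
        i0, i1 = self.index_range(t0, t1)
        if i1 <= i0:
            raise ValidationError(f"empty slice for span [{t0}, {t1}) s")
        return TimeSeries(
            self.values[i0:i1].copy(),
            self.sampling_rate,
            start_time=self.start_time + i0 / self.sampling_rate,
            units=self.units,
        )

    def with_values(self, values: np.ndarray, units: str | None = None) -> "TimeSeries":
        """Same time base, new sample values (and optionally new units)."""
        return TimeSeries(values, self.sampling_rate, self.start_time, units or self.units)


@dataclass
class SubjectProfile:
    """Physical characteristics of one subject.

    ``sex`` is coded 0 = female, 1 = male.  ``heart_rate`` is the session-level
    resting heart rate in beats per minute.  BMI must be consistent with height
    and weight to within 0.1 kg/m^2.
    """

    subject_id: str
    age: float
    height: float
    weight: float
    sex: int
    bmi: float
    heart_rate: float

    def violations(self) -> list[str]:
        v: list[str] = []
        if not self.age > 0:
            v.append(f"profile {self.subject_id}: age must be > 0, got {self.age}")
        if not self.height > 0:
            v.append(f"profile {self.subject_id}: height must be > 0, got {self.height}")
        if not self.weight > 0:
            v.append(f"profile {self.subject_id}: weight must be > 0, got {self.weight}")
        if self.sex not in (0, 1):
            v.append(f"profile {self.subject_id}: sex must be 0 or 1, got {self.sex}")
        if self.height > 0 and self.weight > 0:
            true_bmi = self.weight / (self.height / 100.0) ** 2
            if abs(self.bmi - true_bmi) >= 0.1:
                v.append(
                    f"profile {self.subject_id}: bmi {self.bmi:.2f} inconsistent with "
                    f"height/weight (true bmi {true_bmi:.2f})"
                )
        return v


@dataclass
class ReferenceReading:
    """One cuff reference measurement: systolic over diastolic, in mmHg."""

    time: float
    sbp: float
    dbp: float

    def violations(self) -> list[str]:
        if not (self.sbp > self.dbp > 0):
            return [
                f"reference at t={self.time:g}s: requires sbp > dbp > 0, "
                f"got sbp={self.sbp:g}, dbp={self.dbp:g}"
            ]
        return []


@dataclass
class SensorSession:
    """One wearing session: six channels + subject profile + cuff references."""

    session_id: str
    profile: SubjectProfile
    ppg_palmar: TimeSeries
    ppg_dorsal: TimeSeries
    iface_palmar_v: TimeSeries
    iface_dorsal_v: TimeSeries
    temp_palmar: TimeSeries
    temp_dorsal: TimeSeries
    references: list[ReferenceReading] = field(default_factory=list)

    def channels(self) -> dict[str, TimeSeries]:
        return {name: getattr(self, name) for name in CHANNEL_NAMES}

    @property
    def duration(self) -> float:
        """Common covered duration (seconds) across all channels."""
        return min(ch.end_time for ch in self.channels().values()) - max(
            ch.start_time for ch in self.channels().values()
        )


@dataclass
class Dataset:
    """A cohort of sessions; one subject may own several sessions."""

    sessions: list[SensorSession]

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self) -> Iterator[SensorSession]:
        return iter(self.sessions)

    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            seen.setdefault(s.profile.subject_id, None)
        return list(seen)

    def session_index(self) -> list[tuple[str, str]]:
        """(session_id, subject_id) pairs, in cohort order."""
        return [(s.session_id, s.profile.subject_id) for s in self.sessions]

    def violations(self) -> list[str]:
        v: list[str] = []
        ids = [s.session_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            v.append("dataset: session_ids are not unique")
        for s in self.sessions:
            if not s.references:
                v.append(f"dataset: session {s.session_id} has no reference readings")
        return v


def validate_session(
    session: SensorSession,
    ppg_rate: float = PPG_RATE,
    iface_rate: float = IFACE_RATE,
) -> list[str]:
    """Check every session invariant; return human-readable violations.

    Never raises: an empty list means the session is well formed.  Expected
    channel rates default to the wearable's 1 kHz (PPG) and 125 Hz (interface
    and temperature) but are configurable.
    """
    v: list[str] = []
    v.extend(session.profile.violations())
    for r in session.references:
        v.extend(r.violations())

    expected = {
        "ppg_palmar": ppg_rate,
        "ppg_dorsal": ppg_rate,
        "iface_palmar_v": iface_rate,
        "iface_dorsal_v": iface_rate,
        "temp_palmar": iface_rate,
        "temp_dorsal": iface_rate,
    }
    chans = session.channels()
    for name, rate in expected.items():
        got = chans[name].sampling_rate
        if not math.isclose(got, rate, rel_tol=1e-6):
            v.append(f"channel {name}: sampling_rate {got:g} Hz, expected {rate:g} Hz")

    starts = [ch.start_time for ch in chans.values()]
    if max(starts) - min(starts) >= 1.0 / iface_rate:
        v.append(
            f"channel start-time skew {max(starts) - min(starts):.4f} s exceeds "
            f"one sample at {iface_rate:g} Hz"
        )
    return v


# --------------------------------------------------------------------------
# Serialization: metadata.json + one CSV per channel (or a zip of the same).
# --------------------------------------------------------------------------

def _profile_to_dict(p: SubjectProfile) -> dict:
    return {
        "subject_id": p.subject_id,
        "age": p.age,
        "height": p.height,
        "weight": p.weight,
        "sex": p.sex,
        "bmi": p.bmi,
        "heart_rate": p.heart_rate,
    }


def _profile_from_dict(d: dict) -> SubjectProfile:
    return SubjectProfile(
        subject_id=str(d["subject_id"]),
        age=float(d["age"]),
        height=float(d["height"]),
        weight=float(d["weight"]),
        sex=int(d["sex"]),
        bmi=float(d["bmi"]),
        heart_rate=float(d["heart_rate"]),
    )


def write_session(session: SensorSession, path: str | Path) -> None:
    """Write a session as a directory of ``metadata.json`` + channel CSVs.

    Values are written with 17 significant digits, so 64-bit floats round-trip
    bit-exactly.  Channels containing non-finite values are refused (the
    :class:`TimeSeries` constructor enforces this; the check here guards
    against in-place mutation after construction).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "session_id": session.session_id,
        "profile": _profile_to_dict(session.profile),
        "references": [
            {"time": r.time, "sbp": r.sbp, "dbp": r.dbp} for r in session.references
        ],
        "channels": {},
    }
    for name, ch in session.channels().items():
        if not np.isfinite(ch.values).all():
            raise ValidationError(f"channel {name}: non-finite values, refusing to write")
        meta["channels"][name] = {
            "sampling_rate": ch.sampling_rate,
            "start_time": ch.start_time,
            "units": ch.units,
            "n_samples": len(ch),
        }
        with open(path / f"{name}.csv", "w") as fh:
            fh.write("time_s,value\n")
            t = ch.times()
            for ti, vi in zip(t.tolist(), ch.values.tolist()):
                fh.write(f"{ti!r},{vi!r}\n")
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_channel_csv(text: str, name: str, meta: dict) -> TimeSeries:
    rows = text.strip().splitlines()
    if not rows or rows[0].strip() != "time_s,value":
        raise ValidationError(f"channel {name}: expected header 'time_s,value'")
    data = np.loadtxt(io.StringIO("\n".join(rows[1:])), delimiter=",", ndmin=2)
    times, values = data[:, 0], data[:, 1]
    rate = float(meta["sampling_rate"])
    if len(times) > 1:
        dt = np.median(np.diff(times))
        if not math.isclose(dt, 1.0 / rate, rel_tol=1e-3):
            raise ValidationError(
                f"channel {name}: metadata says {rate:g} Hz but timestamps step "
                f"{dt:g} s (~{1.0 / dt:g} Hz)"
            )
    return TimeSeries(
        values,
        sampling_rate=rate,
        start_time=float(meta["start_time"]),
        units=str(meta["units"]),
    )


def read_session(path: str | Path) -> SensorSession:
    """Read a session directory (or a zip archive of one) back into memory.

    Raises
    ------
    IOError
        If a channel file named in the metadata manifest is missing.
    ValidationError
        If a channel's timestamps disagree with its declared sampling rate, or
        the stored session violates a type invariant.
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".zip":
        texts: dict[str, str] = {}
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                name = Path(info.filename).name
                if name:
                    texts[name] = zf.read(info).decode()
    elif path.is_dir():
        texts = None  # lazy file access below
    else:
        raise IOError(f"no session directory or zip archive at {path}")

    def load(fname: str) -> str:
        if texts is not None:
            if fname not in texts:
                raise IOError(f"session {path}: missing file {fname}")
            return texts[fname]
        fpath = path / fname
        if not fpath.exists():
            raise IOError(f"session {path}: missing file {fname}")
        return fpath.read_text()

    meta = json.loads(load("metadata.json"))
    channels: dict[str, TimeSeries] = {}
    for name in CHANNEL_NAMES:
        if name not in meta["channels"]:
            raise ValidationError(f"metadata lacks channel manifest entry {name!r}")
        try:
            text = load(f"{name}.csv")
        except IOError:
            raise IOError(f"session {path}: missing channel file for {name!r}") from None
        channels[name] = _read_channel_csv(text, name, meta["channels"][name])

    session = SensorSession(
        session_id=str(meta["session_id"]),
        profile=_profile_from_dict(meta["profile"]),
        references=[
            ReferenceReading(float(r["time"]), float(r["sbp"]), float(r["dbp"]))
            for r in meta["references"]
        ],
        **channels,
    )
    return session


def write_dataset_manifest(dataset_paths: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write a cohort manifest CSV with columns session_id, subject_id, path."""
    with open(path, "w") as fh:
        fh.write("session_id,subject_id,path\n")
        for sid, subj, p in dataset_paths:
            fh.write(f"{sid},{subj},{p}\n")


def read_dataset_manifest(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a cohort manifest CSV written by :func:`write_dataset_manifest`."""
    rows = Path(path).read_text().strip().splitlines()
    if not rows or rows[0].strip() != "session_id,subject_id,path":
        raise ValidationError("manifest must start with header session_id,subject_id,path")
    out = []
    for line in rows[1:]:
        sid, subj, p = line.split(",", 2)
        out.append((sid, subj, p))
    return out
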