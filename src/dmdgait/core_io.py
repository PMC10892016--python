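"""Data model and on-disk formats for waist-accelerometer gait sessions.

A recording session is one participant performing one timed walking or
running activity while wearing a single triaxial accelerometer at the
waist (x = vertical, y = mediolateral, z = anteroposterior).  Sessions
are stored as 4-column CSV files; a cohort is described by a JSON or
YAML manifest that links participants to their session files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

#: Standard gravity, m/s² per g, used when a session file declares units of g.
G_STANDARD = 9.80665

#: Time-grid uniformity tolerance, seconds.
TIME_TOL = 1e-6


class Group(str, Enum):
    """Cohort arm: Duchenne muscular dystrophy or typically developing."""

    DMD = "DMD"
    TD = "TD"


class Activity(str, Enum):
    """The eight timed walking/running activities.

    SC-L1..SC-L5 are 25 m speed-calibration efforts from slowest walk to
    run; 6MWT is the six-minute walk test; 100MRW the 100 m fast
    walk/jog/run; FW a free walk.
    """

    SC_L1 = "SC-L1"
    SC_L2 = "SC-L2"
    SC_L3 = "SC-L3"
    SC_L4 = "SC-L4"
    SC_L5 = "SC-L5"
    MWT6 = "6MWT"
    MRW100 = "100MRW"
    FW = "FW"


ACTIVITIES = list(Activity)


class ValidationError(ValueError):
    """A domain invariant was violated."""


class ParseError(ValueError):
    """A file could not be parsed."""


@dataclass(frozen=True)
class Participant:
    """One child in the cohort.

    Parameters
    ----------
    id : str
        Opaque identifier.
    group : Group
        DMD or TD.
    age : float
        Years.
    height : float
        Standing height in meters.
    weight : float
        Body mass in kilograms.
    nsaa : int
        Northstar Ambulatory Assessment total score, 0-34
        (34 = full functional mobility).
    """

    id: str
    group: Group
    age: float
    height: float
    weight: float
    nsaa: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        if not self.height > 0:
            raise ValidationError(f"participant {self.id}: height must be > 0")
        if not self.weight > 0:
            raise ValidationError(f"participant {self.id}: weight must be > 0")
        if not 0 <= self.nsaa <= 34:
            raise ValidationError(
                f"participant {self.id}: nsaa {self.nsaa} outside [0, 34]"
            )


@dataclass(frozen=True)
class ActivityMeta:
    """Course metadata for one activity effort.

    distance is the course length in meters, duration the effort time in
    seconds; observed_steps is the evaluator's manual step count when one
    was recorded.
    """

    activity: Activity
    distance: float
    duration: float
    observed_steps: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "activity", Activity(self.activity))
        if self.distance < 0:
            raise ValidationError("distance must be >= 0")
        if not self.duration > 0:
            raise ValidationError("duration must be > 0")
        if self.observed_steps is not None and self.observed_steps < 1:
            raise ValidationError("observed_steps must be >= 1 when present")


@dataclass
class AccelSession:
    """One triaxial acceleration recording.

    Axis convention: ``ax`` vertical, ``ay`` mediolateral, ``az``
    anteroposterior.  Units are m/s²; the time grid must be uniform at
    the stated sampling rate ``fs``.
    """

    participant_id: str
    activity: Activity
    fs: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.activity = Activity(self.activity)
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n) or n < 2:
            raise ValidationError("t, ax, ay, az must share length >= 2")
        if not self.fs > 0:
            raise ValidationError("fs must be > 0")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - 1.0 / self.fs) > TIME_TOL):
            raise ValidationError(
                f"time grid not uniform at 1/fs within {TIME_TOL} s"
            )
        for name, a in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"{name} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) stack of the three axes, columns x, y, z."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class Cohort:
    """All participants plus their (session, metadata) pairs."""

    participants: list[Participant]
    sessions: list[tuple[AccelSession, ActivityMeta]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate participant id")
        self._by_id = {p.id: p for p in self.participants}
        seen: set[tuple[str, Activity]] = set()
        for sess, meta in self.sessions:
            if sess.participant_id not in self._by_id:
                raise ValidationError(
                    f"session references unknown participant {sess.participant_id!r}"
                )
            if sess.activity != meta.activity:
                raise ValidationError(
                    f"session/meta activity mismatch for {sess.participant_id}"
                )
            key = (sess.participant_id, sess.activity)
            if key in seen:
                raise ValidationError(
                    f"duplicate session for {sess.participant_id}/{sess.activity.value}"
                )
            seen.add(key)

    def participant(self, pid: str) -> Participant:
        return self._by_id[pid]

    def sessions_for_activity(
        self, activity: Activity
    ) -> list[tuple[AccelSession, ActivityMeta]]:
        activity = Activity(activity)
        return [(s, m) for s, m in self.sessions if s.activity == activity]


# ---------------------------------------------------------------------------
# session CSV round-trip

_HEADER = "time_s,ax,ay,az"
_UNIT_FACTORS = {"m_s2": 1.0, "g": G_STANDARD}


def read_session(
    path: str | Path,
    meta: ActivityMeta,
    participant_id: str = "",
    fs: Optional[float] = None,
) -> AccelSession:
    """Read one session CSV.

    The file holds a ``time_s,ax,ay,az`` header, optionally preceded by a
    ``# units: g`` or ``# units: m_s2`` comment; values declared in g are
    converted to m/s² on read.  The sampling rate is inferred from the
    time column unless given.
    """
    path = Path(path)
    factor = 1.0
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].lstrip().startswith("#"):
        comment = lines[i].lstrip("# ").strip()
        if comment.lower().startswith("units:"):
            unit = comment.split(":", 1)[1].strip()
            if unit not in _UNIT_FACTORS:
                raise ParseError(f"{path}: unknown unit declaration {unit!r}")
            factor = _UNIT_FACTORS[unit]
        i += 1
    if i >= len(lines) or lines[i].strip() != _HEADER:
        raise ParseError(f"{path}: expected header {_HEADER!r}")
    for lineno, line in enumerate(lines[i + 1 :], start=i + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 comma-separated values")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if len(rows) < 2:
        raise ParseError(f"{path}: fewer than 2 samples")
    arr = np.asarray(rows)
    t = arr[:, 0]
    if fs is None:
        dt = np.median(np.diff(t))
        fs = 1.0 / dt
        # snap to a round rate when the grid is effectively integral Hz
        if abs(fs - round(fs)) < 1e-6 * fs:
            fs = float(round(fs))
    return AccelSession(
        participant_id=participant_id,
        activity=meta.activity,
        fs=fs,
        t=t,
        ax=arr[:, 1] * factor,
        ay=arr[:, 2] * factor,
        az=arr[:, 3] * factor,
    )


def write_session(session: AccelSession, path: str | Path) -> None:
    """Write a session as CSV at full float precision (deterministic bytes)."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("# units: m_s2\n")
        fh.write(_HEADER + "\n")
        for ti, xi, yi, zi in zip(session.t, session.ax, session.ay, session.az):
            fh.write(f"{float(ti)!r},{float(xi)!r},{float(yi)!r},{float(zi)!r}\n")


# ---------------------------------------------------------------------------
# cohort manifest

def load_cohort(manifest: str | Path) -> Cohort:
    """Load a cohort from a JSON/YAML manifest.

    Schema::

        participants: [{id, group, age, height_m, weight_kg, nsaa}]
        sessions: [{participant_id, activity, distance_m, duration_s,
                    observed_steps, file}]

    Session file paths are resolved relative to the manifest.
    """
    manifest = Path(manifest)
    with open(manifest) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "participants" not in doc:
        raise ParseError(f"{manifest}: manifest must map 'participants'/'sessions'")
    participants = [
        Participant(
            id=str(p["id"]),
            group=Group(p["group"]),
            age=float(p.get("age", float("nan"))),
            height=float(p["height_m"]),
            weight=float(p["weight_kg"]),
            nsaa=int(p["nsaa"]),
        )
        for p in doc["participants"]
    ]
    known = {p.id for p in participants}
    sessions = []
    for s in doc.get("sessions", []):
        pid = str(s["participant_id"])
        if pid not in known:
            raise ValidationError(f"session references unknown id {pid!r}")
        meta = ActivityMeta(
            activity=Activity(s["activity"]),
            distance=float(s["distance_m"]),
            duration=float(s["duration_s"]),
            observed_steps=(
                int(s["observed_steps"]) if s.get("observed_steps") is not None else None
            ),
        )
        sess = read_session(manifest.parent / s["file"], meta, participant_id=pid)
        sessions.append((sess, meta))
    return Cohort(participants=participants, sessions=sessions)


def save_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort directory (manifest.json + one CSV per session).

    Returns the manifest path.  Inverse of :func:`load_cohort` up to
    floating-point round-trip.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sess, meta in cohort.sessions:
        fname = f"{sess.participant_id}_{sess.activity.value}.csv".replace("/", "-")
        write_session(sess, directory / fname)
        entries.append(
            {
                "participant_id": sess.participant_id,
                "activity": sess.activity.value,
                "distance_m": meta.distance,
                "duration_s": meta.duration,
                "observed_steps": meta.observed_steps,
                "file": fname,
            }
        )
    doc = {
        "participants": [
            {
                "id": p.id,
                "group": p.group.value,
                "age": p.age,
                "height_m": p.height,
                "weight_kg": p.weight,
                "nsaa": p.nsaa,
            }
            for p in cohort.participants
        ],
        "sessions": entries,
    }
    manifest = directory / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return manifest
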