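"""The eight temporospatial gait clinical features (CFs) per session.

For each activity effort we compute:

- ``sp`` — speed: (distance / duration) / height, fraction of standing
  height per second;
- ``sf`` — step frequency: steps / duration, steps per second;
- ``sl`` — step length: (distance / steps) / height, fraction of height;
- ``tp`` — total power: sum over axes of the full-band PSD integral,
  divided by body mass;
- ``vp``, ``mp``, ``ap`` — percent of total power in the vertical,
  mediolateral, and anteroposterior axes;
- ``fi`` — force index: anteroposterior PSD integral divided by body
  mass and by the un-normalized mean speed (m/s).

Step counts come from the accelerometer peak detector by default, or the
evaluator's manual count when one was recorded.  tp and fi are defined by
the PSD-integral operations above; the conventional W/kg and N/kg labels
and the table scalings (1e-6, 1e-3) are presentation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core_io import AccelSession, ActivityMeta, Cohort, Participant
from .signal_processing import PSD, band_power, count_steps, session_psds


class StepSource(str, Enum):
    DETECTED = "detected"
    OBSERVED = "observed"


FEATURE_NAMES = ["sp", "sf", "sl", "tp", "vp", "mp", "ap", "fi"]


@dataclass
class GaitFeatures:
    """The eight CFs for one (participant, activity) session."""

    sp: float
    sf: float
    sl: float
    tp: float
    vp: float
    mp: float
    ap: float
    fi: float
    n_steps: int
    source: StepSource

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


def speed(meta: ActivityMeta, participant: Participant) -> float:
    """Height-normalized speed: (distance/duration)/height."""
    if not meta.duration > 0:
        raise ValueError("duration must be > 0")
    return (meta.distance / meta.duration) / participant.height


def step_frequency(n_steps: int, duration: float) -> float:
    """Cadence in steps per second."""
    if not duration > 0:
        raise ValueError("duration must be > 0")
    return n_steps / duration


def step_length(meta: ActivityMeta, n_steps: int, participant: Participant) -> float:
    """Height-normalized step length: (distance/steps)/height."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return (meta.distance / n_steps) / participant.height


def total_power(
    psd_x: PSD, psd_y: PSD, psd_z: PSD, participant: Participant
) -> float:
    """Sum of per-axis full-band PSD integrals, normalized by body mass."""
    if not (
        np.array_equal(psd_x.freqs, psd_y.freqs)
        and np.array_equal(psd_x.freqs, psd_z.freqs)
    ):
        raise ValueError("PSDs must share a frequency grid")
    return (
        band_power(psd_x) + band_power(psd_y) + band_power(psd_z)
    ) / participant.weight


def axial_power_pct(psd_axis: PSD, tp: float, participant: Participant) -> float:
    """Percent of total power carried by one axis."""
    if not tp > 0:
        raise ValueError("tp must be > 0; axial percentages undefined at tp == 0")
    return 100.0 * (band_power(psd_axis) / participant.weight) / tp


def force_index(psd_z: PSD, participant: Participant, sp_abs: float) -> float:
    """Anteroposterior PSD integral over (mass × mean speed in m/s)."""
    if not sp_abs > 0:
        raise ValueError("mean speed must be > 0")
    return (band_power(psd_z) / participant.weight) / sp_abs


def extract_features(
    session: AccelSession,
    meta: ActivityMeta,
    participant: Participant,
    step_source: StepSource = StepSource.DETECTED,
) -> GaitFeatures:
    """Compute all eight CFs for one session.

    With ``step_source == OBSERVED`` the evaluator's manual count replaces
    the peak-detector count (it must be present in ``meta``).  A session
    with zero signal power yields tp = 0 and NaN axial percentages.
    """
    step_source = StepSource(step_source)
    if step_source is StepSource.OBSERVED:
        if meta.observed_steps is None:
            raise ValueError("observed step count requested but not recorded")
        n_steps = meta.observed_steps
    else:
        n_steps = count_steps(session)

    sp = speed(meta, participant)
    sf = step_frequency(n_steps, meta.duration)
    sl = step_length(meta, n_steps, participant) if n_steps >= 1 else float("nan")

    psd_x, psd_y, psd_z = session_psds(session)
    tp = total_power(psd_x, psd_y, psd_z, participant)
    if tp > 0:
        vp = axial_power_pct(psd_x, tp, participant)
        mp = axial_power_pct(psd_y, tp, participant)
        ap = axial_power_pct(psd_z, tp, participant)
    else:
        vp = mp = ap = float("nan")

    sp_abs = meta.distance / meta.duration
    fi = force_index(psd_z, participant, sp_abs) if sp_abs > 0 else float("nan")

    return GaitFeatures(
        sp=sp, sf=sf, sl=sl, tp=tp, vp=vp, mp=mp, ap=ap, fi=fi,
        n_steps=n_steps, source=step_source,
    )


def build_feature_table(
    cohort: Cohort, step_source: StepSource = StepSource.DETECTED
) -> pd.DataFrame:
    """One row of CFs per (participant, activity) session.

    Columns: participant_id, activity, group, nsaa, the eight CFs,
    n_steps, step_source.  Rows are sorted (participant, activity) so
    regeneration is deterministic.  Participants missing a session simply
    contribute no row for that activity (a warning notes the gap).
    """
    rows = []
    have = {(s.participant_id, s.activity) for s, _ in cohort.sessions}
    for p in cohort.participants:
        missing = [a.value for a in _cohort_activities(cohort) if (p.id, a) not in have]
        if missing:
            warnings.warn(
                f"participant {p.id} has no session for: {', '.join(missing)}",
                stacklevel=2,
            )
    for sess, meta in cohort.sessions:
        p = cohort.participant(sess.participant_id)
        feats = extract_features(sess, meta, p, step_source)
        rows.append(
            {
                "participant_id": p.id,
                "activity": sess.activity.value,
                "group": p.group.value,
                "nsaa": p.nsaa,
                **feats.as_dict(),
                "n_steps": feats.n_steps,
                "step_source": feats.source.value,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["participant_id", "activity"]).reset_index(drop=True)
    return table


def _cohort_activities(cohort: Cohort):
    return sorted({s.activity for s, _ in cohort.sessions}, key=lambda a: a.value)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """CSV export, rounded to 6 significant digits."""
    out = table.copy()
    for col in FEATURE_NAMES:
        out[col] = out[col].map(lambda v: float(f"{v:.6g}") if np.isfinite(v) else v)
    out.to_csv(path, index=False)
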