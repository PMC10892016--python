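"""Deep-learning branch (DL-RAW): window-level CNN plus majority voting.

Each activity recording is sliced into fixed-length non-overlapping
time windows (0.3-2.5 s at 100 Hz); a small 1-D CNN classifies every
window as DMD or TD, and the subject-level call is the majority vote
over that subject's windows (a tie resolves to DMD: a screening tool
favors sensitivity).  Evaluation is leave-one-subject-out: the network
and its normalization statistics see no window from the held-out child.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cml import ClassificationRun
from .cnn import WindowCNNClassifier
from .core_io import AccelSession, Activity, Cohort, Group
from .signal_processing import PROTOCOL_TW_SAMPLES, TimeWindow, slice_windows


@dataclass
class DLConfig:
    """Configuration of one DL-RAW run."""

    tw_samples: int = 100
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    architecture: tuple = ((16, 5), (32, 5))  # (filters, kernel) per conv block

    def make_model(self) -> WindowCNNClassifier:
        filters = tuple(f for f, _ in self.architecture)
        kernel = self.architecture[0][1]
        return WindowCNNClassifier(
            n_filters=filters,
            kernel_size=kernel,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            random_state=self.seed,
        )


@dataclass
class SubjectVote:
    """Window votes for one participant."""

    participant_id: str
    n_tw: int
    frac_dmd: float
    final_label: Group

    def __post_init__(self) -> None:
        assert 0.0 <= self.frac_dmd <= 1.0


def _stack(windows: Sequence[TimeWindow]):
    X = np.stack([w.samples for w in windows])
    y = np.array([w.label.value for w in windows], dtype=object)
    return X, y


def train_tw_model(
    windows: Sequence[TimeWindow], config: DLConfig
) -> WindowCNNClassifier:
    """Fit the window CNN on labeled training windows.

    Per-channel standardization statistics are computed from these
    windows only; training is deterministic given ``config.seed``.
    """
    if not windows:
        raise ValueError("no training windows")
    X, y = _stack(windows)
    if len(set(y)) < 2:
        raise ValueError("training windows contain a single class")
    return config.make_model().fit(X, y)


def vote(labels: Sequence[str]) -> tuple[float, Group]:
    """Majority vote over window labels; frac_dmd ties resolve to DMD."""
    labels = list(labels)
    frac_dmd = sum(1 for v in labels if v == "DMD") / len(labels)
    return frac_dmd, Group.DMD if frac_dmd >= 0.5 else Group.TD


def predict_subject(
    model: WindowCNNClassifier, session: AccelSession, config: DLConfig
) -> SubjectVote:
    """Slice one session and vote the subject label over window predictions."""
    windows = slice_windows(session, config.tw_samples)
    if not windows:
        raise ValueError(
            f"session too short: needs at least {config.tw_samples} samples "
            f"({config.tw_samples / session.fs:.2f} s)"
        )
    X = np.stack([w.samples for w in windows])
    preds = model.predict(X)
    frac_dmd, final = vote(preds)
    return SubjectVote(
        participant_id=session.participant_id,
        n_tw=len(windows),
        frac_dmd=frac_dmd,
        final_label=final,
    )


def cohort_windows(cohort: Cohort, activity: Activity, tw_samples: int):
    """All windows of one activity, labeled with each participant's group."""
    out: list[TimeWindow] = []
    for sess, _meta in cohort.sessions_for_activity(activity):
        label = cohort.participant(sess.participant_id).group
        out.extend(slice_windows(sess, tw_samples, label=label))
    return out


def loso_evaluate_dl(
    cohort: Cohort, activity: Activity, config: DLConfig
) -> ClassificationRun:
    """Leave-one-subject-out evaluation of the DL-RAW branch.

    For each fold the CNN is trained on every window from the other
    participants and the held-out participant is labeled by majority
    vote over their windows.  Returns subject-level accuracy plus the
    per-subject votes (in ``fold_predictions`` / ``subject_votes``).
    """
    activity = Activity(activity)
    sessions = {
        s.participant_id: s for s, _ in cohort.sessions_for_activity(activity)
    }
    pids = sorted(sessions)
    labels = {pid: cohort.participant(pid).group.value for pid in pids}
    n_per_class = pd.Series(list(labels.values())).value_counts()
    if len(n_per_class) < 2 or n_per_class.min() < 2:
        raise ValueError("need at least 2 participants per class with this activity")

    all_windows = cohort_windows(cohort, activity, config.tw_samples)
    fold_predictions: dict[str, str] = {}
    fold_train_ids: dict[str, frozenset] = {}
    votes: dict[str, SubjectVote] = {}
    for pid in pids:
        train = [w for w in all_windows if w.participant_id != pid]
        train_pids = frozenset(w.participant_id for w in train)
        assert pid not in train_pids  # leakage guard
        model = train_tw_model(train, config)
        sv = predict_subject(model, sessions[pid], config)
        votes[pid] = sv
        fold_predictions[pid] = sv.final_label.value
        fold_train_ids[pid] = train_pids

    accuracy = float(np.mean([fold_predictions[p] == labels[p] for p in pids]))
    run = ClassificationRun(
        config=config,
        fold_predictions=fold_predictions,
        true_labels=labels,
        accuracy=accuracy,
        fold_train_ids=fold_train_ids,
    )
    run.subject_votes = votes  # type: ignore[attr-defined]
    run.assert_no_leakage()
    return run


def sweep_tw(
    cohort: Cohort,
    activity: Activity,
    tw_sizes: Sequence[int] = PROTOCOL_TW_SAMPLES,
    config: DLConfig | None = None,
) -> pd.DataFrame:
    """DL-RAW accuracy for each window length; one report row per size."""
    base = config or DLConfig()
    rows = []
    for tw in tw_sizes:
        cfg = DLConfig(
            tw_samples=tw,
            epochs=base.epochs,
            batch_size=base.batch_size,
            learning_rate=base.learning_rate,
            seed=base.seed,
            architecture=base.architecture,
        )
        run = loso_evaluate_dl(cohort, activity, cfg)
        rows.append(
            {
                "activity": Activity(activity).value,
                "tw_samples": tw,
                "accuracy_pct": 100.0 * run.accuracy,
            }
        )
    return pd.DataFrame(rows)


def votes_table(run: ClassificationRun) -> pd.DataFrame:
    """Per-subject vote CSV shape: participant_id, n_tw, frac_dmd, final_label."""
    votes = getattr(run, "subject_votes", {})
    return pd.DataFrame(
        [
            {
                "participant_id": v.participant_id,
                "n_tw": v.n_tw,
                "frac_dmd": v.frac_dmd,
                "final_label": v.final_label.value,
            }
            for v in votes.values()
        ]
    )
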