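"""Plotting helpers for the standard report figures.

These produce the usual views of the analysis — raw-signal and spectrum
panels per axis, accuracy bars per activity, LDA score vs step length —
on whatever cohort (real or synthetic) was processed.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .core_io import AccelSession
from .signal_processing import session_psds


def plot_session(session: AccelSession, ax=None):
    """Three stacked time-series panels (x, y, z) plus per-axis PSDs."""
    fig, axes = plt.subplots(2, 3, figsize=(12, 5), constrained_layout=True)
    psds = session_psds(session)
    names = ["vertical (x)", "mediolateral (y)", "anteroposterior (z)"]
    for i, (series, psd, name) in enumerate(
        zip((session.ax, session.ay, session.az), psds, names)
    ):
        axes[0, i].plot(session.t, series, lw=0.5)
        axes[0, i].set_title(name)
        axes[0, i].set_xlabel("time (s)")
        axes[0, i].set_ylabel("accel (m/s²)")
        axes[1, i].plot(psd.freqs, psd.density, lw=0.7)
        axes[1, i].set_xlim(0, 12)
        axes[1, i].set_xlabel("frequency (Hz)")
        axes[1, i].set_ylabel("PSD ((m/s²)²/Hz)")
    return fig


def plot_accuracy_by_activity(grid: pd.DataFrame):
    """Best accuracy per activity for each projection column of a CML sweep."""
    fig, ax = plt.subplots(figsize=(8, 4), constrained_layout=True)
    best = (
        grid.groupby(["activity", "projection"])["accuracy_pct"].max().unstack()
    )
    best.plot.bar(ax=ax)
    ax.set_ylabel("LOSO accuracy (%)")
    ax.set_ylim(0, 105)
    ax.legend(title="projection")
    return fig


def plot_lda_vs_step_length(scores: pd.DataFrame, table: pd.DataFrame,
                            activity: str | None = None):
    """Scatter of the 1-D LDA coordinate against height-normalized step
    length, colored by group (DMD positive by convention)."""
    sub = table if activity is None else table[table["activity"] == activity]
    merged = sub.merge(scores[["participant_id", "LDA1"]], on="participant_id")
    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    for group, color in (("TD", "tab:blue"), ("DMD", "tab:red")):
        m = merged[merged["group"] == group]
        ax.scatter(m["sl"], m["LDA1"], s=18, c=color, label=group, alpha=0.8)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("step length (fraction of height)")
    ax.set_ylabel("LDA coordinate")
    ax.legend()
    return fig
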