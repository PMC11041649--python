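"""Gaze-position towardness and behavioural measures.

Towardness collapses the left/right structure of the gaze bias into one
signed time course: the trial-averaged horizontal gaze position on
right-cued trials minus left-cued trials, divided by two.  Positive values
mean gaze is biased toward the encoded side of the cued memory item.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gaze_io import IntegrityError
from .preprocess import EpochSet

__all__ = [
    "CondTimecourse",
    "towardness",
    "delay_average",
    "mirror_epochs",
    "reproduction_error",
    "behaviour_summary",
]


@dataclass
class CondTimecourse:
    """Per-participant, per-condition time course of a scalar gaze metric."""

    participant: int | str
    condition: str
    metric: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise IntegrityError("time axis and values differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "condition": self.condition,
                "metric": self.metric,
                "time_ms": self.times,
                "value": self.values,
            }
        )


def towardness(epochs: EpochSet, condition: str | None = None) -> CondTimecourse:
    """T(t) = (mean x, right-cued − mean x, left-cued) / 2, rightward positive."""
    meta = epochs.meta
    if condition is not None:
        sel = meta["condition"] == condition
        epochs = epochs.select(sel.to_numpy())
        meta = epochs.meta
    right = meta["cued_side"].to_numpy() == "right"
    if right.all() or (~right).all():
        raise IntegrityError("towardness needs trials with both cued sides")
    values = (epochs.x[right].mean(axis=0) - epochs.x[~right].mean(axis=0)) / 2.0
    label = condition if condition is not None else "all"
    return CondTimecourse(
        participant=epochs.participant,
        condition=label,
        metric="towardness",
        times=epochs.times,
        values=values,
    )


def delay_average(tc: CondTimecourse, window: tuple[int, int] = (0, 1500)) -> float:
    """Scalar summary: mean of the time course over the post-cue delay window."""
    sel = (tc.times >= window[0]) & (tc.times < window[1])
    return float(tc.values[sel].mean())


def mirror_epochs(epochs: EpochSet) -> EpochSet:
    """Swap the cued-side labels while leaving the gaze data untouched.

    Relabelling which side was cued negates towardness exactly; mirroring
    the gaze geometry as well (negating x too) would leave it invariant.
    """
    meta = epochs.meta.copy()
    meta["cued_side"] = meta["cued_side"].map({"left": "right", "right": "left"})
    return replace(epochs, meta=meta)


def reproduction_error(reported, target):
    """Minimal angular distance in 180°-circular orientation space, in [0, 90].

    Bars are orientation stimuli, so 0° and 180° are the same orientation;
    uniform guessing therefore gives a mean error of 45°.
    """
    reported = np.asarray(reported, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.any((reported < 0) | (reported >= 180)) or np.any((target < 0) | (target >= 180)):
        raise ValueError("orientations must lie in [0, 180)")
    diff = np.abs(reported - target)
    err = np.minimum(diff, 180.0 - diff)
    return float(err) if err.ndim == 0 else err


def behaviour_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean reproduction error (deg) and response onset (ms) per participant × condition."""
    t = trials.copy()
    if "participant" not in t.columns:
        t["participant"] = 0
    t["reproduction_error"] = reproduction_error(
        t["reported_orientation"].to_numpy(), t["target_orientation"].to_numpy()
    )
    out = (
        t.groupby(["participant", "condition"], sort=True)
        .agg(
            mean_error_deg=("reproduction_error", "mean"),
            mean_response_onset_ms=("response_onset_ms", "mean"),
            n_trials=("trial_id", "count"),
        )
        .reset_index()
    )
    return out
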