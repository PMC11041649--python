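"""Velocity-threshold gaze-shift detection and rate/magnitude time courses.

Detection follows the standard adaptive velocity-threshold scheme for
microsaccades: gaze velocity is estimated with a 5-sample symmetric
difference filter, a per-trial, per-axis threshold is set at ``lambda``
times a median-based velocity SD (so the threshold adapts to the noise
level of each trial), and supra-threshold runs under an elliptic 2-D
criterion that last at least ``min_dur_ms`` become candidate events.
Because memory items are separated exclusively along the horizontal axis,
event displacement and magnitude are horizontal: ``dx`` is the position
difference between offset and onset and events with ``|dx|`` at or below
``min_magnitude_units`` (default 1 unit ≈ 0.08°) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import IntegrityError
from .preprocess import EpochSet

__all__ = [
    "SaccadeParams",
    "SaccadeRateTimecourse",
    "MagnitudeBiasMap",
    "detect_saccades",
    "classify_direction",
    "rate_timecourses",
    "magnitude_bias_map",
    "score_detection",
    "DEFAULT_MAG_EDGES",
]

EVENT_COLUMNS = ["trial_id", "onset_ms", "offset_ms", "dx", "magnitude", "peak_velocity"]

#: Magnitude-bin edges in normalized units: 2 to 110 in steps of 4, half-open.
DEFAULT_MAG_EDGES = np.arange(2, 111, 4)


@dataclass
class SaccadeParams:
    lambda_: float = 5.0
    min_dur_ms: int = 6
    merge_ms: int = 20
    min_magnitude_units: float = 1.0


def _velocity(p: np.ndarray, dt_s: float) -> np.ndarray:
    """5-sample symmetric-difference velocity (units/s); edges zero-padded."""
    v = np.zeros_like(p)
    v[2:-2] = (p[4:] + p[3:-1] - p[1:-3] - p[:-4]) / (6.0 * dt_s)
    return v


def _median_sd(v: np.ndarray) -> float:
    inner = v[2:-2]
    var = np.median(inner**2) - np.median(inner) ** 2
    return float(np.sqrt(max(var, 1e-12)))


def detect_saccades(epochs: EpochSet, params: SaccadeParams | None = None) -> pd.DataFrame:
    """Detect gaze shifts per trial; returns one row per retained event.

    Onset/offset times are on the epoch time axis (ms relative to cue).
    Events overlapping the epoch edges (where the velocity filter is
    undefined) are dropped.
    """
    params = params or SaccadeParams()
    step = int(epochs.times[1] - epochs.times[0]) if epochs.times.size > 1 else 1
    dt_s = step / 1000.0
    n_time = epochs.times.size
    if n_time < 10:
        raise IntegrityError("epoch shorter than the velocity filter window")
    min_dur = max(1, round(params.min_dur_ms / step))
    merge = round(params.merge_ms / step)

    rows = []
    for i in range(epochs.n_trials):
        x = epochs.x[i]
        y = epochs.y[i]
        vx = _velocity(x, dt_s)
        vy = _velocity(y, dt_s)
        ex = params.lambda_ * _median_sd(vx)
        ey = params.lambda_ * _median_sd(vy)
        crit = (vx / ex) ** 2 + (vy / ey) ** 2 > 1.0
        crit[:2] = crit[-2:] = False
        edges = np.flatnonzero(np.diff(np.concatenate(([0], crit.view(np.int8), [0]))))
        runs = [
            (s, e)
            for s, e in zip(edges[::2], edges[1::2] - 1)  # inclusive sample indices
            if e - s + 1 >= min_dur
        ]
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        tid = epochs.meta.iloc[i]["trial_id"]
        for s, e in merged:
            if s <= 2 or e >= n_time - 3:
                continue
            dx = float(x[e] - x[s])
            if abs(dx) <= params.min_magnitude_units:
                continue
            rows.append(
                {
                    "trial_id": tid,
                    "onset_ms": int(epochs.times[s]),
                    "offset_ms": int(epochs.times[e]),
                    "dx": dx,
                    "magnitude": abs(dx),
                    "peak_velocity": float(np.max(np.hypot(vx[s : e + 1], vy[s : e + 1]))),
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def classify_direction(events: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Label each event toward/away relative to the trial's cued side."""
    sides = trials.set_index("trial_id")["cued_side"]
    ev = events.copy()
    cued = ev["trial_id"].map(sides)
    if cued.isna().any():
        raise IntegrityError("event refers to a trial_id absent from the trial table")
    toward = (ev["dx"] > 0) == (cued == "right")
    ev["direction"] = np.where(toward, "toward", "away")
    return ev


@dataclass
class SaccadeRateTimecourse:
    """Toward/away saccade rates (Hz) and their contrast over the epoch."""

    participant: int | str
    condition: str
    times: np.ndarray
    toward_hz: np.ndarray
    away_hz: np.ndarray
    smooth_ms: int = 100

    @property
    def effect_hz(self) -> np.ndarray:
        return self.toward_hz - self.away_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "condition": self.condition,
                "time_ms": self.times,
                "toward_hz": self.toward_hz,
                "away_hz": self.away_hz,
                "effect_hz": self.effect_hz,
            }
        )


def _smooth(rate: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the epoch edges."""
    if window <= 1:
        return rate
    return (
        pd.Series(rate).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )


def _onset_rate(
    events: pd.DataFrame, epochs: EpochSet, mask: np.ndarray, smooth_ms: int
) -> np.ndarray:
    step = int(epochs.times[1] - epochs.times[0])
    fs = 1000.0 / step
    idx = ((events.loc[mask, "onset_ms"].to_numpy() - int(epochs.times[0])) // step).astype(int)
    counts = np.bincount(idx, minlength=epochs.times.size).astype(float)
    rate = counts / epochs.n_trials * fs
    return _smooth(rate, round(smooth_ms / step))


def rate_timecourses(
    events: pd.DataFrame,
    epochs: EpochSet,
    smooth_ms: int = 100,
    condition: str = "all",
) -> SaccadeRateTimecourse:
    """Per-millisecond toward/away onset rates (Hz), 100 ms moving average."""
    if epochs.n_trials == 0:
        raise IntegrityError("rate time courses need at least one trial")
    if "direction" not in events.columns:
        raise IntegrityError("events must be classified before computing rates")
    toward = _onset_rate(events, epochs, (events["direction"] == "toward").to_numpy(), smooth_ms)
    away = _onset_rate(events, epochs, (events["direction"] == "away").to_numpy(), smooth_ms)
    return SaccadeRateTimecourse(
        participant=epochs.participant,
        condition=condition,
        times=epochs.times,
        toward_hz=toward,
        away_hz=away,
        smooth_ms=smooth_ms,
    )


@dataclass
class MagnitudeBiasMap:
    """Toward-minus-away rate resolved by time and saccade magnitude bin."""

    times: np.ndarray
    edges: np.ndarray          # bin edges, half-open [edges[i], edges[i+1])
    effect_hz: np.ndarray      # (n_bins, n_time)
    smooth_ms: int = 100

    def band_effect(self, lo: float, hi: float) -> np.ndarray:
        """Summed effect over all bins fully inside [lo, hi)."""
        sel = (self.edges[:-1] >= lo) & (self.edges[1:] <= hi)
        return self.effect_hz[sel].sum(axis=0)


def magnitude_bias_map(
    events: pd.DataFrame,
    epochs: EpochSet,
    edges: np.ndarray = DEFAULT_MAG_EDGES,
    smooth_ms: int = 100,
) -> MagnitudeBiasMap:
    """Time × magnitude map of the directional saccade bias.

    By convention this analysis runs on trials filtered only by the
    response-time rule (not the gaze-excursion rule), so that large shifts
    revisiting the encoded locations remain visible.
    """
    if "direction" not in events.columns:
        raise IntegrityError("events must be classified before computing the map")
    n_bins = edges.size - 1
    eff = np.empty((n_bins, epochs.times.size))
    mag = events["magnitude"].to_numpy()
    for b in range(n_bins):
        in_bin = (mag >= edges[b]) & (mag < edges[b + 1])
        toward = _onset_rate(
            events, epochs, in_bin & (events["direction"] == "toward").to_numpy(), smooth_ms
        )
        away = _onset_rate(
            events, epochs, in_bin & (events["direction"] == "away").to_numpy(), smooth_ms
        )
        eff[b] = toward - away
    return MagnitudeBiasMap(times=epochs.times, edges=np.asarray(edges), effect_hz=eff, smooth_ms=smooth_ms)


def score_detection(
    events: pd.DataFrame,
    truth: pd.DataFrame,
    tol_ms: int = 20,
    min_amplitude: float = 0.0,
) -> pd.DataFrame:
    """Match detected events to injected ground-truth saccades per trial.

    Each injected saccade (optionally restricted to ``amplitude >=
    min_amplitude``) is matched to the nearest unmatched detection in the
    same trial within ``tol_ms`` of its onset.  Returns the truth table
    with ``matched`` and ``onset_error_ms`` columns, from which recall and
    onset accuracy are computed.
    """
    truth = truth[truth["amplitude"] >= min_amplitude].copy()
    truth["matched"] = False
    truth["onset_error_ms"] = np.nan
    for tid, tgrp in truth.groupby("trial_id"):
        det = events[events["trial_id"] == tid]
        used = np.zeros(len(det), dtype=bool)
        onsets = det["onset_ms"].to_numpy()
        for idx, inj in tgrp.iterrows():
            if onsets.size == 0:
                continue
            err = np.abs(onsets - inj["onset_rel_cue"])
            err[used] = np.iinfo(np.int32).max
            j = int(np.argmin(err))
            if err[j] <= tol_ms:
                used[j] = True
                truth.loc[idx, "matched"] = True
                truth.loc[idx, "onset_error_ms"] = float(onsets[j] - inj["onset_rel_cue"])
    return truth
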