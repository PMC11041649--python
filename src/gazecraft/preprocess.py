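"""Raw recording -> normalized, baseline-corrected, exclusion-filtered epochs.

Processing order mirrors standard fixational eye-tracking practice:

1. blink interpolation (cubic spline across padded missing-sample gaps),
2. calibration fit (per-axis affine from per-point median gaze to the
   nominal target coordinates; fixation maps to 0, the stimulus centres
   at ±8 degrees map to ±100 normalized units),
3. epoching around the retro-cue (−500…1499 ms) with per-trial baseline
   correction over the 500 ms preceding the cue,
4. trial exclusion: gaze excursions beyond 50 normalized units in the
   post-cue window, and iteratively, response onsets slower than
   mean + 4 SD of the remaining trials.

Conventions: rightward/up positive, 0 = fixation, time 0 = cue onset,
all intervals half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .gaze_io import ExclusionReport, GazeEvent, IntegrityError, RawGazeRecording

__all__ = [
    "CalibrationMap",
    "EpochSet",
    "CALIB_TARGETS",
    "interpolate_blinks",
    "fit_calibration",
    "normalize",
    "epoch_and_baseline",
    "exclude_trials",
]

log = logging.getLogger(__name__)

#: Nominal 7-point calibration layout in normalized units: central fixation,
#: the two stimulus centres (±100 horizontal), two vertical and two diagonal
#: points.  The fit only assumes these coordinates are known.
CALIB_TARGETS: dict[int, tuple[float, float]] = {
    1: (0.0, 0.0),
    2: (-100.0, 0.0),
    3: (100.0, 0.0),
    4: (0.0, 60.0),
    5: (0.0, -60.0),
    6: (-70.0, 45.0),
    7: (70.0, -45.0),
}


@dataclass
class CalibrationMap:
    """Per-axis affine map from tracker units to the normalized ±100 frame.

    ``normalized = gain * (raw - offset)`` per axis; ``gain`` has units of
    normalized units per tracker unit and ``offset`` is the raw value that
    maps to 0 (central fixation).
    """

    gain_x: float
    offset_x: float
    gain_y: float
    offset_y: float
    residuals: pd.DataFrame | None = None
    targets: dict[int, tuple[float, float]] = field(default_factory=lambda: dict(CALIB_TARGETS))

    def apply_x(self, raw: np.ndarray) -> np.ndarray:
        return self.gain_x * (np.asarray(raw, dtype=float) - self.offset_x)

    def apply_y(self, raw: np.ndarray) -> np.ndarray:
        return self.gain_y * (np.asarray(raw, dtype=float) - self.offset_y)

    def invert_x(self, norm: np.ndarray) -> np.ndarray:
        return np.asarray(norm, dtype=float) / self.gain_x + self.offset_x

    def invert_y(self, norm: np.ndarray) -> np.ndarray:
        return np.asarray(norm, dtype=float) / self.gain_y + self.offset_y


@dataclass
class EpochSet:
    """Trials × time × {x, y} normalized gaze around the retro-cue.

    ``data`` has shape ``(n_trials, n_time, 2)`` (channel 0 horizontal,
    1 vertical), ``times`` is the millisecond axis relative to cue onset,
    and ``meta`` carries one trial-table row per epoch (same order).
    """

    data: np.ndarray
    times: np.ndarray
    meta: pd.DataFrame
    participant: int | str = 0
    baseline_window: tuple[int, int] = (-500, 0)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.meta):
            raise IntegrityError("metadata rows do not match epoch count")
        if self.data.shape[1] != self.times.size:
            raise IntegrityError("time axis does not match epoch length")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.data[:, :, 0]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, :, 1]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self, data=self.data[mask], meta=self.meta.iloc[mask].reset_index(drop=True)
        )


def _blink_intervals(recording: RawGazeRecording) -> list[tuple[int, int]]:
    """Blink spans from markers, plus any unmarked missing-sample runs."""
    spans: list[tuple[int, int]] = []
    start = None
    for ev in recording.events:
        if ev.name == "BLINK_START":
            start = ev.time
        elif ev.name == "BLINK_END" and start is not None:
            spans.append((start, ev.time))
            start = None
    missing = np.zeros(recording.n_samples, dtype=bool)
    for ch in recording.channels().values():
        missing |= np.isnan(ch)
    t0 = int(recording.time[0])
    for s, e in spans:
        missing[max(0, s - t0) : e - t0 + 1] = False
    if missing.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            spans.append((int(recording.time[s]), int(recording.time[e - 1])))
    return sorted(spans)


def interpolate_blinks(
    recording: RawGazeRecording,
    pad_ms: int = 50,
    anchor_ms: int = 100,
    max_gap_ms: int = 500,
) -> RawGazeRecording:
    """Spline-interpolate gaze across blinks.

    Each blink is widened by ``pad_ms`` on both sides (peri-blink samples are
    typically corrupted by partial pupil occlusion) and filled with a cubic
    spline anchored on the ``anchor_ms`` of clean data flanking the padded
    gap.  Gaps longer than ``max_gap_ms`` are filled with the nearest valid
    value and recorded in ``unrecoverable_gaps`` so overlapping trials can be
    excluded downstream; blinks abutting a recording edge fall back to
    nearest-value fill as well.
    """
    rec = recording.copy()
    step = round(1000 / rec.sampling_rate)
    t0 = int(rec.time[0])
    n = rec.n_samples
    for start, end in _blink_intervals(recording):
        lo = max(0, (start - t0) // step - pad_ms // step)
        hi = min(n - 1, (end - t0) // step + pad_ms // step)
        gap_ms = (hi - lo + 1) * step
        left = np.arange(max(0, lo - anchor_ms // step), lo)
        right = np.arange(hi + 1, min(n, hi + 1 + anchor_ms // step))
        long_gap = gap_ms > max_gap_ms
        at_edge = left.size == 0 or right.size == 0
        for name, ch in rec.channels().items():
            if long_gap or at_edge:
                fill = np.nan
                if left.size:
                    fill = ch[left[-1]]
                elif right.size:
                    fill = ch[right[0]]
                ch[lo : hi + 1] = fill
            else:
                anchors = np.concatenate((left, right))
                valid = anchors[~np.isnan(ch[anchors])]
                if valid.size < 4:
                    ch[lo : hi + 1] = ch[valid[-1]] if valid.size else np.nan
                    continue
                spline = CubicSpline(rec.time[valid], ch[valid])
                ch[lo : hi + 1] = spline(rec.time[lo : hi + 1])
        if long_gap:
            rec.unrecoverable_gaps.append((int(rec.time[lo]), int(rec.time[hi])))
            log.info("gap %d-%d ms exceeds %d ms; nearest-fill, flagged", start, end, max_gap_ms)
        elif at_edge:
            log.info("blink %d-%d ms abuts recording edge; nearest-value fill", start, end)
    return rec


def _point_medians(
    recording: RawGazeRecording, window_ms: tuple[int, int] = (400, 1000)
) -> pd.DataFrame:
    """Median binocular gaze per calibration point over ``window_ms`` post-onset."""
    rows = []
    t0 = int(recording.time[0])
    step = round(1000 / recording.sampling_rate)
    for ev in recording.events_named("CALIB_POINT"):
        k = int(ev.arg)
        lo = (ev.time - t0 + window_ms[0]) // step
        hi = (ev.time - t0 + window_ms[1]) // step
        ch = recording.channels()
        x = np.nanmedian(
            np.concatenate((ch["left_x"][lo:hi], ch["right_x"][lo:hi]))
        )
        y = np.nanmedian(
            np.concatenate((ch["left_y"][lo:hi], ch["right_y"][lo:hi]))
        )
        rows.append({"point": k, "raw_x": x, "raw_y": y})
    return pd.DataFrame(rows)


def fit_calibration(
    recording: RawGazeRecording,
    nominal_targets: dict[int, tuple[float, float]] | None = None,
    window_ms: tuple[int, int] = (400, 1000),
) -> CalibrationMap:
    """Least-squares affine fit from per-point median gaze to nominal coordinates.

    The median gaze over 400–1000 ms after each calibration-point onset is
    regressed, per axis, onto the known target coordinates.  Requires at
    least two distinct target positions per axis.
    """
    targets = dict(nominal_targets or CALIB_TARGETS)
    med = _point_medians(recording, window_ms)
    if med.empty:
        raise IntegrityError("no CALIB_POINT events in recording")
    med["tx"] = med["point"].map(lambda k: targets[k][0])
    med["ty"] = med["point"].map(lambda k: targets[k][1])

    def fit_axis(raw: np.ndarray, nominal: np.ndarray) -> tuple[float, float]:
        if np.unique(nominal).size < 2 or np.ptp(raw) == 0:
            raise IntegrityError("degenerate calibration targets: axis not identifiable")
        gain, intercept = np.polyfit(raw, nominal, 1)
        return float(gain), float(-intercept / gain)

    gx, ox = fit_axis(med["raw_x"].to_numpy(), med["tx"].to_numpy())
    gy, oy = fit_axis(med["raw_y"].to_numpy(), med["ty"].to_numpy())
    cmap = CalibrationMap(gain_x=gx, offset_x=ox, gain_y=gy, offset_y=oy, targets=targets)
    med["resid_x"] = cmap.apply_x(med["raw_x"].to_numpy()) - med["tx"]
    med["resid_y"] = cmap.apply_y(med["raw_y"].to_numpy()) - med["ty"]
    cmap.residuals = med
    return cmap


def normalize(recording: RawGazeRecording, cmap: CalibrationMap) -> RawGazeRecording:
    """Map all four channels into the normalized ±100 frame (100 units ≡ 8°)."""
    if recording.units == "normalized":
        raise IntegrityError("recording is already normalized")
    rec = recording.copy()
    rec.left_x = cmap.apply_x(rec.left_x)
    rec.right_x = cmap.apply_x(rec.right_x)
    rec.left_y = cmap.apply_y(rec.left_y)
    rec.right_y = cmap.apply_y(rec.right_y)
    rec.units = "normalized"
    return rec


def epoch_and_baseline(
    recording: RawGazeRecording,
    trials: pd.DataFrame,
    epoch_window: tuple[int, int] = (-500, 1500),
    baseline_window: tuple[int, int] = (-500, 0),
    participant: int | str = 0,
) -> EpochSet:
    """Cut per-trial epochs around the cue and baseline-correct each channel.

    Binocular combination: left and right eye averaged per axis (a single
    missing eye falls back to the other).  The per-trial mean over the
    baseline window is subtracted from each channel.  Trials whose epoch
    exceeds the recording are dropped with a log entry.
    """
    step = round(1000 / recording.sampling_rate)
    t0 = int(recording.time[0])
    n = recording.n_samples
    times = np.arange(epoch_window[0], epoch_window[1], step)
    b0 = (baseline_window[0] - epoch_window[0]) // step
    b1 = (baseline_window[1] - epoch_window[0]) // step
    x = np.nanmean(np.stack((recording.left_x, recording.right_x)), axis=0)
    y = np.nanmean(np.stack((recording.left_y, recording.right_y)), axis=0)

    epochs, kept, gap_flags = [], [], []
    for _, tr in trials.iterrows():
        lo = (int(tr["cue_onset"]) - t0 + epoch_window[0]) // step
        hi = lo + times.size
        if lo < 0 or hi > n:
            log.info("trial %s too close to recording edge; dropped", tr["trial_id"])
            continue
        seg = np.stack((x[lo:hi], y[lo:hi]), axis=-1)
        seg = seg - seg[b0:b1].mean(axis=0, keepdims=True)
        epochs.append(seg)
        kept.append(tr)
        span = (int(recording.time[lo]), int(recording.time[hi - 1]))
        gap_flags.append(
            any(s <= span[1] and e >= span[0] for s, e in recording.unrecoverable_gaps)
        )
    meta = pd.DataFrame(kept).reset_index(drop=True)
    meta["flag_gaze_gap"] = gap_flags
    data = np.stack(epochs) if epochs else np.empty((0, times.size, 2))
    return EpochSet(
        data=data,
        times=times,
        meta=meta,
        participant=participant,
        baseline_window=baseline_window,
    )


def exclude_trials(
    epochs: EpochSet,
    gaze_limit_units: float = 50.0,
    rt_sd_mult: float = 4.0,
    gaze_window: tuple[int, int] = (0, 1500),
    apply_gaze: bool = True,
    apply_rt: bool = True,
) -> tuple[EpochSet, ExclusionReport]:
    """Drop gaze-excursion and slow-response trials; report per-condition counts.

    Gaze rule: any post-cue sample with ``|x| > gaze_limit_units`` (or an
    unrecoverable blink gap) voids the trial.  Response rule: trials with
    response onset above mean + ``rt_sd_mult``·SD of the remaining trials,
    re-applied until no outlier remains.  The operation is idempotent.
    """
    if epochs.n_trials == 0:
        raise IntegrityError("cannot run exclusions on an empty epoch set")
    in_win = (epochs.times >= gaze_window[0]) & (epochs.times < gaze_window[1])
    gaze_bad = np.zeros(epochs.n_trials, dtype=bool)
    if apply_gaze:
        gaze_bad = np.nanmax(np.abs(epochs.x[:, in_win]), axis=1) > gaze_limit_units
        if "flag_gaze_gap" in epochs.meta:
            gaze_bad |= epochs.meta["flag_gaze_gap"].to_numpy(dtype=bool)

    rt = epochs.meta["response_onset_ms"].to_numpy(dtype=float)
    rt_bad = np.zeros(epochs.n_trials, dtype=bool)
    if apply_rt:
        keep = ~gaze_bad
        while True:
            vals = rt[keep & ~rt_bad]
            if vals.size < 2:
                break
            cut = vals.mean() + rt_sd_mult * vals.std(ddof=1)
            new = keep & ~rt_bad & (rt > cut)
            if not new.any():
                break
            rt_bad |= new

    report = ExclusionReport()
    for cond, grp in epochs.meta.groupby("condition", sort=True):
        idx = grp.index.to_numpy()
        report.add(
            str(cond),
            n_total=idx.size,
            n_excluded_gaze=int(gaze_bad[idx].sum()),
            n_excluded_rt=int(rt_bad[idx].sum()),
        )
    kept = ~(gaze_bad | rt_bad)
    for tid in epochs.meta.loc[gaze_bad, "trial_id"]:
        log.info("trial %s excluded: gaze excursion", tid)
    for tid in epochs.meta.loc[rt_bad, "trial_id"]:
        log.info("trial %s excluded: slow response onset", tid)
    if not kept.any():
        raise IntegrityError("all trials excluded")
    return epochs.select(kept), report
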