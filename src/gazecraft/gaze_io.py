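"""Plain-text gaze recording format, trial tables and report writing.

The recording dialect is a line-oriented plain-text format loosely modelled
on the ASCII exports of video-based eye trackers:

* header lines ``#RATE <hz>`` and ``#UNITS raw|normalized``;
* sample lines ``t lx ly rx ry`` (whitespace-separated, ``.`` marks a
  missing sample, e.g. during a blink);
* event lines ``E t LABEL [arg]`` interleaved in time order.

Times are integer milliseconds from recording start; at the default
1000 Hz sampling rate one sample per millisecond.  Event labels used by
the pipeline are ``CALIB_POINT <k>``, ``CUE_ONSET <trial_id>``,
``RESPONSE_ONSET <trial_id>`` and ``BLINK_START``/``BLINK_END``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GazeEvent",
    "RawGazeRecording",
    "ExclusionReport",
    "ParseError",
    "IntegrityError",
    "read_recording",
    "write_recording",
    "read_trials",
    "write_trials",
    "write_report",
    "TRIAL_COLUMNS",
]


class ParseError(ValueError):
    """A line of a recording file could not be parsed."""


class IntegrityError(ValueError):
    """A recording violates a structural invariant."""


@dataclass(frozen=True)
class GazeEvent:
    """A time-stamped marker; ``label`` includes any argument (e.g. ``CUE_ONSET 17``)."""

    time: int
    label: str

    @property
    def name(self) -> str:
        return self.label.split()[0]

    @property
    def arg(self) -> str | None:
        parts = self.label.split(maxsplit=1)
        return parts[1] if len(parts) > 1 else None


@dataclass
class RawGazeRecording:
    """Continuous binocular gaze samples plus event markers.

    Channels are float arrays with NaN marking missing samples.  ``units``
    is ``"raw"`` (tracker units) until calibration normalization maps the
    data onto the ±100 stimulus frame.
    """

    time: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    events: list[GazeEvent] = field(default_factory=list)
    sampling_rate: int = 1000
    units: str = "raw"
    # intervals (start_ms, end_ms) that blink interpolation could not repair;
    # trials overlapping these are later counted as gaze exclusions
    unrecoverable_gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        for ch in ("left_x", "left_y", "right_x", "right_y"):
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=np.float64))

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def channels(self) -> dict[str, np.ndarray]:
        return {
            "left_x": self.left_x,
            "left_y": self.left_y,
            "right_x": self.right_x,
            "right_y": self.right_y,
        }

    def events_named(self, name: str) -> list[GazeEvent]:
        return [e for e in self.events if e.name == name]

    def copy(self) -> "RawGazeRecording":
        return replace(
            self,
            time=self.time.copy(),
            left_x=self.left_x.copy(),
            left_y=self.left_y.copy(),
            right_x=self.right_x.copy(),
            right_y=self.right_y.copy(),
            events=list(self.events),
            unrecoverable_gaps=list(self.unrecoverable_gaps),
        )

    def validate(self) -> None:
        n = self.n_samples
        for name, ch in self.channels().items():
            if ch.size != n:
                raise IntegrityError(f"channel {name} has {ch.size} samples, expected {n}")
        if n > 1:
            steps = np.diff(self.time)
            expected = round(1000 / self.sampling_rate)
            if not np.all(steps == expected):
                bad = int(np.flatnonzero(steps != expected)[0])
                raise IntegrityError(
                    f"time axis not on a constant {expected} ms grid near sample {bad}"
                )
        if self.units not in ("raw", "normalized"):
            raise IntegrityError(f"unknown units {self.units!r}")
        open_blink = None
        for ev in self.events:
            if ev.name == "BLINK_START":
                if open_blink is not None:
                    raise IntegrityError(f"nested BLINK_START at t={ev.time}")
                open_blink = ev.time
            elif ev.name == "BLINK_END":
                if open_blink is None or ev.time < open_blink:
                    raise IntegrityError(f"BLINK_END without matching start at t={ev.time}")
                open_blink = None
        if open_blink is not None:
            raise IntegrityError(f"BLINK_START at t={open_blink} never closed")


def _fmt(v: float) -> str:
    return "." if np.isnan(v) else f"{v:.4f}"


def write_recording(recording: RawGazeRecording, path: str | Path) -> None:
    """Serialize a recording in the canonical dialect (round-trips exactly)."""
    recording.validate()
    path = Path(path)
    events = sorted(
        enumerate(recording.events), key=lambda ie: (ie[1].time, ie[0])
    )  # stable in original order at equal times
    lines: list[str] = [f"#RATE {recording.sampling_rate}", f"#UNITS {recording.units}"]
    ei = 0
    for i, t in enumerate(recording.time):
        while ei < len(events) and events[ei][1].time <= t:
            ev = events[ei][1]
            lines.append(f"E {ev.time} {ev.label}")
            ei += 1
        lines.append(
            f"{t} {_fmt(recording.left_x[i])} {_fmt(recording.left_y[i])}"
            f" {_fmt(recording.right_x[i])} {_fmt(recording.right_y[i])}"
        )
    for _, ev in events[ei:]:
        lines.append(f"E {ev.time} {ev.label}")
    path.write_text("\n".join(lines) + "\n")


def read_recording(path: str | Path) -> RawGazeRecording:
    """Parse a recording file; malformed lines raise :class:`ParseError` with a line number."""
    path = Path(path)
    rate = 1000
    units = "raw"
    times: list[int] = []
    cols: tuple[list[float], ...] = ([], [], [], [])
    events: list[GazeEvent] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            if line.startswith("#RATE"):
                rate = int(line.split()[1])
            elif line.startswith("#UNITS"):
                units = line.split()[1]
            elif line.startswith("#"):
                continue
            elif line.startswith("E "):
                parts = line.split(maxsplit=2)
                events.append(GazeEvent(time=int(parts[1]), label=parts[2]))
            else:
                parts = line.split()
                if len(parts) != 5:
                    raise ValueError(f"expected 5 fields, got {len(parts)}")
                times.append(int(parts[0]))
                for c, p in zip(cols, parts[1:]):
                    c.append(np.nan if p == "." else float(p))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path.name}:{lineno}: malformed line {raw!r} ({exc})") from exc
    rec = RawGazeRecording(
        time=np.array(times, dtype=np.int64),
        left_x=np.array(cols[0]),
        left_y=np.array(cols[1]),
        right_x=np.array(cols[2]),
        right_y=np.array(cols[3]),
        events=events,
        sampling_rate=rate,
        units=units,
    )
    rec.validate()
    return rec


TRIAL_COLUMNS = [
    "trial_id",
    "experiment",
    "condition",
    "trial_subtype",
    "cued_side",
    "cue_onset",
    "target_orientation",
    "reported_orientation",
    "response_onset_ms",
    "block",
]


def validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise IntegrityError(f"trial table missing columns {missing}")
    if not trials["cued_side"].isin(["left", "right"]).all():
        raise IntegrityError("cued_side must be 'left' or 'right'")
    for col in ("target_orientation", "reported_orientation"):
        v = trials[col].to_numpy(dtype=float)
        if np.any((v < 0) | (v >= 180)):
            raise IntegrityError(f"{col} outside [0, 180)")
    if np.any(trials["response_onset_ms"].to_numpy(dtype=float) <= 0):
        raise IntegrityError("response_onset_ms must be positive")


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trials(trials)
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    validate_trials(trials)
    return trials


@dataclass
class ExclusionReport:
    """Per-condition tally of trials dropped by the gaze and response-time rules."""

    conditions: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, condition: str, n_total: int, n_excluded_gaze: int, n_excluded_rt: int) -> None:
        if n_excluded_gaze + n_excluded_rt > n_total:
            raise ValueError("excluded more trials than exist")
        self.conditions[condition] = {
            "n_total": int(n_total),
            "n_excluded_gaze": int(n_excluded_gaze),
            "n_excluded_rt": int(n_excluded_rt),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, c in self.conditions.items():
            n = c["n_total"]
            rows.append(
                {
                    "condition": cond,
                    **c,
                    "pct_gaze": 100.0 * c["n_excluded_gaze"] / n if n else 0.0,
                    "pct_rt": 100.0 * c["n_excluded_rt"] / n if n else 0.0,
                    "pct_total": 100.0 * (c["n_excluded_gaze"] + c["n_excluded_rt"]) / n
                    if n
                    else 0.0,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "condition",
                "n_total",
                "n_excluded_gaze",
                "n_excluded_rt",
                "pct_gaze",
                "pct_rt",
                "pct_total",
            ],
        )


def write_report(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    summary: Mapping | None = None,
) -> None:
    """Write one CSV per table plus an optional ``summary.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        if not isinstance(table, pd.DataFrame):
            raise TypeError(f"table {name!r} is not a DataFrame")
        table.to_csv(outdir / f"{name}.csv", index=False)
    if summary is not None:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
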