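"""Generative model of fixational gaze during a retro-cue working-memory task.

A simulated session contains a 7-point calibration sweep followed by a
sequence of trials.  Gaze is synthesized in the normalized stimulus frame
(fixation 0, stimulus centres ±100 ≡ ±8°) as the sum of

* slow ocular drift (an Ornstein–Uhlenbeck process),
* white measurement noise, independent per eye,
* microsaccades: Poisson-rate events with log-normal amplitudes and a
  smooth 20 ms sigmoidal displacement profile,
* blinks: missing-sample spans with corrupted padding on both sides,

and then mapped to tracker units through a per-axis affine so that the
calibration fit has something to recover.

During the 1500 ms after each retro-cue the probability that a
microsaccade is directed toward the cued item's encoded side follows a
gamma-shaped bump: chance (0.5) before ``bias_latency_ms``, rising to
``bias_peak_p_toward``.  Each biased-window saccade may spawn a
return-to-centre saccade after an exponential delay, which produces the
late negative lobe of the toward-minus-away rate and makes the *position*
bias (towardness) peak and then decay.  ``bias_peak_ms`` parameterizes the
peak time of the expected position bias; the underlying rate-bump peak is
derived from it by deconvolving the return-saccade kernel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_io import GazeEvent, RawGazeRecording
from .metrics import CondTimecourse
from .preprocess import CALIB_TARGETS, CalibrationMap

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_calibration",
    "simulate_null_group",
    "null_differences",
]

E1_SUBTYPES = {
    "sim_early": "simultaneous",
    "sim_late": "simultaneous",
    "sim_both": "simultaneous",
    "seq_left_first": "sequential",
    "seq_right_first": "sequential",
}


@dataclass
class SimConfig:
    """Study conditions and free parameters of the generative model.

    Trial counts, geometry and timing follow the task design (Experiment 1:
    five presentation subtypes × 100 trials in 10 blocks of 50; Experiment 2:
    480 trials over 5 colour and 5 order blocks; items at ±8° ≡ ±100 units;
    250 ms encoding displays separated by 750 ms, 250 ms cue, 1250 ms
    delays).  The oculomotor parameters (baseline microsaccade rate,
    amplitude distribution, drift and noise scales) are free parameters of
    the generator with field-plausible defaults.
    """

    experiment: int = 1
    n_trials_per_subtype: int = 100          # E1: 5 subtypes -> 500 trials
    n_trials_e2: int = 480                   # E2 total, over 10 blocks
    trials_per_block: int = 50
    eccentricity_units: float = 100.0
    iti_ms: tuple[int, int] = (500, 800)
    encoding_ms: int = 250
    isi_ms: int = 750
    cue_ms: int = 250
    delay_ms: int = 1250
    trial_tail_ms: int = 200
    # direction-bias model
    bias_latency_ms: float = 300.0
    bias_peak_ms: float = 600.0              # peak time of expected position bias
    bias_peak_p_toward: float = 0.75
    bias_window_ms: int = 1500
    base_msacc_rate_hz: float = 1.5
    amp_median_units: float = 5.0
    amp_sigma_log: float = 0.6
    saccade_dur_ms: int = 20
    min_intersaccade_ms: int = 50      # oculomotor refractory interval
    return_saccade_prob: float = 0.9
    return_delay_mean_ms: float = 300.0
    # drift / noise / blinks
    drift_sd_units: float = 2.0
    drift_theta: float = 0.0002
    noise_sd_units: float = 0.2
    blink_rate_hz: float = 0.04
    blink_dur_ms: int = 100
    blink_pad_ms: int = 50
    # calibration + raw-unit affine (normalized = gain * (raw - offset))
    calib_dwell_ms: int = 1200
    gain_x: float = 0.05
    offset_x: float = 512.0
    gain_y: float = 0.05
    offset_y: float = 512.0
    # behaviour
    report_noise_sd_deg: float = 17.5        # mean |error| = sd*sqrt(2/pi) ~ 14 deg
    rt_median_ms: float = 220.0
    rt_sigma_log: float = 0.25
    sampling_rate: int = 1000

    def validate(self) -> None:
        if not (0.0 <= self.bias_peak_p_toward <= 1.0):
            raise ValueError("bias_peak_p_toward must be in [0, 1]")
        if not (0.0 <= self.return_saccade_prob <= 1.0):
            raise ValueError("return_saccade_prob must be in [0, 1]")
        for name in ("base_msacc_rate_hz", "blink_rate_hz", "noise_sd_units", "drift_sd_units"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bias_latency_ms >= self.bias_peak_ms:
            raise ValueError("bias_latency_ms must precede bias_peak_ms")

    @property
    def n_trials(self) -> int:
        return (
            5 * self.n_trials_per_subtype if self.experiment == 1 else self.n_trials_e2
        )


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline without re-simulation."""

    saccades: pd.DataFrame            # onset_ms, dx, amplitude, kind, trial_id, onset_rel_cue, direction
    blinks: list[tuple[int, int]]
    affine: dict[str, float]
    bias_params: dict[str, float]
    calibration: CalibrationMap | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "saccades": self.saccades.to_dict(orient="list"),
            "blinks": [list(b) for b in self.blinks],
            "affine": self.affine,
            "bias_params": self.bias_params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _smoothstep(n: int) -> np.ndarray:
    """C1 displacement profile over n samples: 0 -> 1 with velocity peak mid-flight."""
    u = np.arange(1, n + 1) / n
    return 3 * u**2 - 2 * u**3


def _direction_bump(t_ms: np.ndarray, latency: float, rate_peak: float, shape: float = 2.0) -> np.ndarray:
    """Gamma-shaped bump in [0, 1]: zero before latency, 1 at ``rate_peak``."""
    u = np.clip((np.asarray(t_ms, dtype=float) - latency) / (rate_peak - latency), 0, None)
    return u**shape * np.exp(shape * (1.0 - u))


def _solve_rate_peak(cfg: SimConfig) -> float:
    """Rate-bump peak time such that the expected position bias peaks at bias_peak_ms.

    The expected position bias is the rate bump convolved with the
    return-saccade survival kernel
    ``S(s) = (1 - q_eff) + q_eff * exp(-(s - d)/tau)`` for ``s > d``, where
    ``d`` is the saccade duration (return delays run from saccade offset)
    and ``q_eff`` discounts the configured return probability by the
    first-order chance that a return candidate is thinned away by the
    refractory interval.  The position-bias peak lags the rate peak, so the
    rate peak is found by bisection.  If no interior peak exists (e.g. no
    return saccades) the rate peak is used directly.
    """
    window = cfg.bias_window_ms
    s = np.arange(window, dtype=float)
    # refractory collisions: a return is dropped if it lands within
    # (saccade_dur + min_isi) of another onset of the ~(1+q)*base-rate stream
    busy = (
        cfg.base_msacc_rate_hz
        * (1.0 + cfg.return_saccade_prob)
        * (cfg.saccade_dur_ms + cfg.min_intersaccade_ms)
        / 1000.0
    )
    q_eff = cfg.return_saccade_prob * float(np.exp(-busy))
    lag = np.maximum(s - cfg.saccade_dur_ms, 0.0)
    kernel = (1.0 - q_eff) + q_eff * np.exp(-lag / cfg.return_delay_mean_ms)

    def pos_peak(rate_peak: float) -> float:
        b = _direction_bump(s, cfg.bias_latency_ms, rate_peak)
        p = np.convolve(b, kernel)[:window]
        return float(np.argmax(p))

    lo = cfg.bias_latency_ms + 5.0
    hi = cfg.bias_peak_ms
    if pos_peak(lo) >= cfg.bias_peak_ms or cfg.return_saccade_prob == 0.0:
        return cfg.bias_peak_ms
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if pos_peak(mid) < cfg.bias_peak_ms:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _build_trials(cfg: SimConfig, rng: np.random.Generator, mirror: bool) -> pd.DataFrame:
    if cfg.experiment == 1:
        subtypes = np.repeat(list(E1_SUBTYPES), cfg.n_trials_per_subtype)
        conditions = np.array([E1_SUBTYPES[s] for s in subtypes])
    else:
        half = cfg.n_trials_e2 // 2
        subtypes = np.array(["colour"] * half + ["order"] * (cfg.n_trials_e2 - half))
        conditions = subtypes.copy()
    n = subtypes.size
    # cued side balanced within subtype
    sides = np.empty(n, dtype=object)
    for st in np.unique(subtypes):
        idx = np.flatnonzero(subtypes == st)
        half = idx.size // 2
        s = np.array(["left"] * half + ["right"] * (idx.size - half), dtype=object)
        rng.shuffle(s)
        sides[idx] = s
    order = rng.permutation(n)
    subtypes, conditions, sides = subtypes[order], conditions[order], sides[order]
    if mirror:
        sides = np.where(sides == "left", "right", "left")

    target = rng.uniform(0, 180, n)
    reported = np.mod(target + rng.normal(0, cfg.report_noise_sd_deg, n), 180.0)
    rt = np.exp(np.log(cfg.rt_median_ms) + cfg.rt_sigma_log * rng.standard_normal(n))
    iti = rng.integers(cfg.iti_ms[0], cfg.iti_ms[1] + 1, n)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "experiment": cfg.experiment,
            "condition": conditions,
            "trial_subtype": subtypes,
            "cued_side": sides,
            "cue_onset": 0,  # filled in once the timeline is laid out
            "target_orientation": target,
            "reported_orientation": reported,
            "response_onset_ms": np.round(rt, 1),
            "block": np.arange(n) // cfg.trials_per_block,
            "iti_ms": iti,
        }
    )


def _ou_drift(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Ornstein–Uhlenbeck drift with stationary SD ``drift_sd_units``."""
    theta = cfg.drift_theta
    innov_sd = cfg.drift_sd_units * np.sqrt(1.0 - (1.0 - theta) ** 2)
    from scipy.signal import lfilter

    white = rng.standard_normal(n) * innov_sd
    return lfilter([1.0], [1.0, -(1.0 - theta)], white)


def _calibration_segment(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[GazeEvent], CalibrationMap]:
    """Normalized-frame gaze for a 7-point sweep plus the generating affine.

    Returns ``(x, y, events, true_map)`` where x/y are the noiseless
    normalized gaze paths (per-eye noise is added by the caller) and the
    map is the ground-truth raw→normalized affine.
    """
    order = rng.permutation(list(CALIB_TARGETS))
    dwell = cfg.calib_dwell_ms
    n = dwell * len(order)
    x = np.zeros(n)
    y = np.zeros(n)
    events = []
    prev = (0.0, 0.0)
    settle = 150
    ramp = _smoothstep(settle)
    for i, k in enumerate(order):
        t0 = i * dwell
        tx, ty = CALIB_TARGETS[int(k)]
        x[t0 : t0 + settle] = prev[0] + (tx - prev[0]) * ramp
        y[t0 : t0 + settle] = prev[1] + (ty - prev[1]) * ramp
        x[t0 + settle : t0 + dwell] = tx
        y[t0 + settle : t0 + dwell] = ty
        events.append(GazeEvent(time=t0, label=f"CALIB_POINT {int(k)}"))
        prev = (tx, ty)
    true_map = CalibrationMap(
        gain_x=cfg.gain_x, offset_x=cfg.offset_x, gain_y=cfg.gain_y, offset_y=cfg.offset_y
    )
    return x, y, events, true_map


def simulate_calibration(
    cfg: SimConfig, seed: int | np.random.SeedSequence
) -> tuple[RawGazeRecording, CalibrationMap]:
    """Standalone 7-point calibration sweep in raw tracker units.

    Gaze settles on each target (with per-eye measurement noise); with
    ``noise_sd_units = 0`` the per-point median equals the affine-mapped
    target exactly, so the calibration fit recovers the generating affine
    in closed form.
    """
    rng = np.random.default_rng(seed)
    x, y, events, true_map = _calibration_segment(cfg, rng)
    n = x.size
    noise = rng.standard_normal((4, n)) * cfg.noise_sd_units
    rec = RawGazeRecording(
        time=np.arange(n, dtype=np.int64),
        left_x=true_map.invert_x(x + noise[0]),
        left_y=true_map.invert_y(y + noise[1]),
        right_x=true_map.invert_x(x + noise[2]),
        right_y=true_map.invert_y(y + noise[3]),
        events=events,
        sampling_rate=cfg.sampling_rate,
        units="raw",
    )
    return rec, true_map


def simulate_session(
    cfg: SimConfig,
    seed: int | np.random.SeedSequence,
    participant: int | str = 0,
    mirror: bool = False,
) -> tuple[RawGazeRecording, pd.DataFrame, GroundTruth]:
    """One participant's full session: raw recording, trial table, ground truth.

    ``mirror=True`` regenerates the identical session with every cued side
    flipped: the same random draws are consumed, so every direction-biased
    saccade reverses sign exactly and the expected towardness is negated.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    trials = _build_trials(cfg, rng, mirror)
    n_trials = len(trials)

    cal_x, cal_y, events, true_map = _calibration_segment(cfg, rng)
    task_start = cal_x.size + 200

    # timeline: cue onset of trial i
    pre_cue = 2 * cfg.encoding_ms + cfg.isi_ms + cfg.delay_ms
    post_cue = cfg.cue_ms + cfg.delay_ms  # cue offset + post-cue delay -> go signal
    cue_onsets = np.empty(n_trials, dtype=np.int64)
    t = task_start
    for i in range(n_trials):
        t += int(trials.loc[i, "iti_ms"])
        cue_onsets[i] = t + pre_cue
        t = cue_onsets[i] + post_cue + int(trials.loc[i, "response_onset_ms"]) + cfg.trial_tail_ms
    trials["cue_onset"] = cue_onsets
    n_samples = t + 500
    trials = trials.drop(columns="iti_ms")

    for i in range(n_trials):
        events.append(GazeEvent(time=int(cue_onsets[i]), label=f"CUE_ONSET {i}"))
        go = int(cue_onsets[i]) + post_cue
        events.append(
            GazeEvent(
                time=go + int(trials.loc[i, "response_onset_ms"]),
                label=f"RESPONSE_ONSET {i}",
            )
        )

    # --- microsaccades over the task period ---------------------------------
    rate_peak = _solve_rate_peak(cfg)
    task_len = n_samples - task_start
    n_sacc = rng.poisson(cfg.base_msacc_rate_hz * task_len / 1000.0)
    onsets = np.sort(rng.integers(task_start, n_samples - cfg.saccade_dur_ms - 1, n_sacc))
    amps = np.exp(np.log(cfg.amp_median_units) + cfg.amp_sigma_log * rng.standard_normal(n_sacc))
    u_dir = rng.random(n_sacc)
    u_ret = rng.random(n_sacc)
    ret_delay = rng.exponential(cfg.return_delay_mean_ms, n_sacc)

    trial_of = np.searchsorted(cue_onsets, onsets, side="right") - 1
    rel = np.where(trial_of >= 0, onsets - cue_onsets[np.clip(trial_of, 0, None)], -1)
    in_window = (trial_of >= 0) & (rel >= 0) & (rel < cfg.bias_window_ms)

    sides_num = np.where(trials["cued_side"].to_numpy() == "right", 1.0, -1.0)
    p_toward = np.full(n_sacc, 0.5)
    p_toward[in_window] = 0.5 + (cfg.bias_peak_p_toward - 0.5) * _direction_bump(
        rel[in_window], cfg.bias_latency_ms, rate_peak
    )
    toward_sign = np.where(in_window, sides_num[np.clip(trial_of, 0, None)], 1.0)
    sign = np.where(u_dir < p_toward, toward_sign, -toward_sign)

    # Event-driven assembly with an oculomotor refractory interval: candidate
    # saccades (Poisson background/biased plus spawned returns) are visited in
    # onset order and dropped if they start within ``min_intersaccade_ms`` of
    # the previous accepted saccade's offset; dropping a parent drops its
    # return.  The same draws are consumed regardless of ``mirror``.
    import heapq

    records = []
    disp_events: list[tuple[int, float]] = []  # (onset_sample, signed dx)
    pending: list[tuple[int, float, int]] = []  # (onset, dx, parent trial)
    last_end = -(10**9)

    def _record(onset: int, dx: float, amp: float, kind: str) -> None:
        tid = int(np.searchsorted(cue_onsets, onset, side="right")) - 1
        r = onset - int(cue_onsets[tid]) if tid >= 0 else -1
        in_win = tid >= 0 and 0 <= r < cfg.bias_window_ms
        records.append(
            {
                "onset_ms": onset,
                "dx": dx,
                "amplitude": amp,
                "kind": kind,
                "trial_id": tid if in_win else -1,
                "onset_rel_cue": int(r) if in_win else -1,
                "direction": (
                    ("toward" if dx * sides_num[tid] > 0 else "away") if in_win else ""
                ),
            }
        )

    j = 0
    while j < n_sacc or pending:
        take_return = pending and (j >= n_sacc or pending[0][0] <= onsets[j])
        if take_return:
            r_on, r_dx, _ = heapq.heappop(pending)
            if r_on < last_end + cfg.min_intersaccade_ms:
                continue
            if r_on >= n_samples - cfg.saccade_dur_ms - 1:
                continue
            disp_events.append((r_on, r_dx))
            _record(r_on, r_dx, abs(r_dx), "return")
            last_end = r_on + cfg.saccade_dur_ms
        else:
            onset = int(onsets[j])
            dx = float(sign[j] * amps[j])
            biased = bool(in_window[j])
            spawn = biased and u_ret[j] < cfg.return_saccade_prob
            delay = float(ret_delay[j])
            j += 1
            if onset < last_end + cfg.min_intersaccade_ms:
                continue
            disp_events.append((onset, dx))
            _record(onset, dx, abs(dx), "biased" if biased else "background")
            last_end = onset + cfg.saccade_dur_ms
            if spawn:
                heapq.heappush(pending, (int(last_end + delay), -dx, onset))

    # --- assemble normalized gaze -------------------------------------------
    x = np.zeros(n_samples)
    y = np.zeros(n_samples)
    x[: cal_x.size] = cal_x
    y[: cal_y.size] = cal_y
    drift_x = _ou_drift(n_samples - cal_x.size, cfg, rng)
    drift_y = _ou_drift(n_samples - cal_x.size, cfg, rng)
    x[cal_x.size :] += drift_x
    y[cal_y.size :] += drift_y
    profile = _smoothstep(cfg.saccade_dur_ms)
    for onset, dx in disp_events:
        x[onset : onset + cfg.saccade_dur_ms] += dx * profile
        x[onset + cfg.saccade_dur_ms :] += dx

    # --- blinks ---------------------------------------------------------------
    blinks: list[tuple[int, int]] = []
    n_blinks = rng.poisson(cfg.blink_rate_hz * task_len / 1000.0)
    blink_onsets = np.sort(rng.integers(task_start, n_samples - cfg.blink_dur_ms - 60, n_blinks))
    pad = cfg.blink_pad_ms
    spike = 30.0 * np.sin(np.linspace(0, np.pi, pad))
    for b0 in blink_onsets:
        b1 = int(b0) + cfg.blink_dur_ms
        if blinks and b0 <= blinks[-1][1] + 2 * pad:
            continue
        y[b0 - pad : b0] += spike
        y[b1 + 1 : b1 + 1 + pad] += spike[::-1]
        blinks.append((int(b0), b1))
        events.append(GazeEvent(time=int(b0), label="BLINK_START"))
        events.append(GazeEvent(time=b1, label="BLINK_END"))

    # --- per-eye noise, raw units, missing samples ----------------------------
    noise = rng.standard_normal((4, n_samples)) * cfg.noise_sd_units
    lx = true_map.invert_x(x + noise[0])
    ly = true_map.invert_y(y + noise[1])
    rx = true_map.invert_x(x + noise[2])
    ry = true_map.invert_y(y + noise[3])
    for b0, b1 in blinks:
        for ch in (lx, ly, rx, ry):
            ch[b0 : b1 + 1] = np.nan

    events.sort(key=lambda e: e.time)
    recording = RawGazeRecording(
        time=np.arange(n_samples, dtype=np.int64),
        left_x=lx,
        left_y=ly,
        right_x=rx,
        right_y=ry,
        events=events,
        sampling_rate=cfg.sampling_rate,
        units="raw",
    )
    truth = GroundTruth(
        saccades=pd.DataFrame(
            records,
            columns=["onset_ms", "dx", "amplitude", "kind", "trial_id", "onset_rel_cue", "direction"],
        ),
        blinks=blinks,
        affine={
            "gain_x": cfg.gain_x,
            "offset_x": cfg.offset_x,
            "gain_y": cfg.gain_y,
            "offset_y": cfg.offset_y,
        },
        bias_params={
            "bias_latency_ms": cfg.bias_latency_ms,
            "bias_peak_ms": cfg.bias_peak_ms,
            "rate_peak_ms": rate_peak,
            "bias_peak_p_toward": cfg.bias_peak_p_toward,
        },
        calibration=true_map,
    )
    return recording, trials, truth


def simulate_null_group(
    cfg: SimConfig,
    n_participants: int,
    seed: int | np.random.SeedSequence,
    n_time: int = 2000,
    sd: float = 1.0,
) -> list[dict[str, CondTimecourse]]:
    """Per-participant condition pairs of i.i.d. Gaussian noise with zero true difference.

    Used to calibrate the familywise error rate of the cluster permutation
    test: any detected cluster is a false positive by construction.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_time)
    group = []
    for p in range(n_participants):
        a, b = rng.standard_normal((2, n_time)) * sd
        group.append(
            {
                "A": CondTimecourse(p, "A", "null", times, a),
                "B": CondTimecourse(p, "B", "null", times, b),
            }
        )
    return group


def null_differences(group: list[dict[str, CondTimecourse]]) -> np.ndarray:
    """Stack per-participant A−B difference curves into an (n, t) matrix."""
    return np.stack([g["A"].values - g["B"].values for g in group])
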