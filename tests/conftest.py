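"""Shared fixtures: small simulated sessions and hand-built epoch sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazecraft.preprocess import (
    EpochSet,
    epoch_and_baseline,
    exclude_trials,
    fit_calibration,
    interpolate_blinks,
    normalize,
)
from gazecraft.simulate import SimConfig, simulate_session


def make_epochs(
    x: np.ndarray,
    cued_sides: list[str] | None = None,
    conditions: list[str] | None = None,
    rts: np.ndarray | None = None,
    t_start: int = -500,
) -> EpochSet:
    """Wrap a (n_trials, n_time) horizontal-gaze array into an EpochSet."""
    x = np.asarray(x, dtype=float)
    n, t = x.shape
    data = np.zeros((n, t, 2))
    data[:, :, 0] = x
    sides = cued_sides if cued_sides is not None else (["right", "left"] * (n // 2 + 1))[:n]
    meta = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "experiment": 1,
            "condition": conditions if conditions is not None else ["sequential"] * n,
            "trial_subtype": "seq_left_first",
            "cued_side": sides,
            "cue_onset": 10_000,
            "target_orientation": 10.0,
            "reported_orientation": 20.0,
            "response_onset_ms": rts if rts is not None else np.full(n, 300.0),
            "block": 0,
        }
    )
    return EpochSet(data=data, times=np.arange(t_start, t_start + t), meta=meta)


def preprocess_session(rec, trials, exclude=True):
    rec = interpolate_blinks(rec)
    rec = normalize(rec, fit_calibration(rec))
    epochs = epoch_and_baseline(rec, trials)
    if not exclude:
        return epochs, None
    return exclude_trials(epochs)


@pytest.fixture(scope="session")
def small_session():
    """Default-parameter session, scaled to 40 trials, with blinks."""
    cfg = SimConfig(n_trials_per_subtype=8)
    rec, trials, truth = simulate_session(cfg, seed=101)
    return cfg, rec, trials, truth


@pytest.fixture(scope="session")
def clean_session():
    """Low-noise, blink-free session used for detector ground-truth scoring."""
    cfg = SimConfig(
        n_trials_per_subtype=16,
        noise_sd_units=0.05,
        drift_sd_units=0.5,
        blink_rate_hz=0.0,
    )
    rec, trials, truth = simulate_session(cfg, seed=202)
    return cfg, rec, trials, truth


@pytest.fixture(scope="session")
def clean_epochs(clean_session):
    _, rec, trials, _ = clean_session
    epochs, _ = preprocess_session(rec, trials)
    return epochs


@pytest.fixture(scope="session")
def biased_group():
    """Eight participants × full-length sessions: group towardness material.

    This is the parameter-recovery workhorse (bias latency/peak, magnitude
    concentration); simulation and preprocessing run once per test session.
    """
    from gazecraft.metrics import towardness
    from gazecraft.saccades import classify_direction, detect_saccades

    cfg = SimConfig()
    curves, all_events, all_epochs = [], [], []
    for p in range(8):
        rec, trials, truth = simulate_session(
            cfg, np.random.SeedSequence(entropy=42, spawn_key=(p,)), participant=p
        )
        filt, _ = preprocess_session(rec, trials)
        curves.append(towardness(filt).values)
        events = classify_direction(detect_saccades(filt), trials)
        all_events.append(events)
        all_epochs.append(filt)
    return cfg, np.stack(curves), all_events, all_epochs
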