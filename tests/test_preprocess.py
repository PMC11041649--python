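"""Blink interpolation, calibration fitting, normalization, epoching, exclusions."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_epochs
from gazecraft.gaze_io import GazeEvent, IntegrityError, RawGazeRecording
from gazecraft.preprocess import (
    CalibrationMap,
    epoch_and_baseline,
    exclude_trials,
    fit_calibration,
    interpolate_blinks,
    normalize,
)


def recording_from_x(x, events=None, units="raw"):
    x = np.asarray(x, dtype=float)
    zeros = np.zeros_like(x)
    return RawGazeRecording(
        time=np.arange(x.size),
        left_x=x.copy(),
        left_y=zeros.copy(),
        right_x=x.copy(),
        right_y=zeros.copy(),
        events=events or [],
        units=units,
    )


class TestBlinkInterpolation:
    def test_no_blinks_leaves_recording_unchanged(self):
        rec = recording_from_x(np.sin(np.arange(2000) / 50.0))
        out = interpolate_blinks(rec)
        np.testing.assert_array_equal(out.left_x, rec.left_x)

    def test_linear_ramp_restored_exactly(self):
        x = np.linspace(0.0, 10.0, 2000)
        rec = recording_from_x(x, events=[GazeEvent(900, "BLINK_START"), GazeEvent(1000, "BLINK_END")])
        for ch in rec.channels().values():
            ch[900:1001] = np.nan
        out = interpolate_blinks(rec, pad_ms=50)
        # cubic spline interpolation reproduces degree-1 polynomials
        np.testing.assert_allclose(out.left_x, x, atol=1e-9)
        # samples outside the padded window untouched
        np.testing.assert_array_equal(out.left_x[:800], x[:800])

    def test_slow_sinusoid_restored_within_analytic_tolerance(self):
        t = np.arange(4000)
        x = 5.0 * np.sin(2 * np.pi * t / 1000.0)
        rec = recording_from_x(x, events=[GazeEvent(1800, "BLINK_START"), GazeEvent(1950, "BLINK_END")])
        for ch in rec.channels().values():
            ch[1800:1951] = np.nan
        out = interpolate_blinks(rec, pad_ms=50)
        masked = slice(1750, 2001)
        err = np.abs(out.left_x[masked] - x[masked]).max()
        # cubic-interpolation remainder bound over the 251 ms knot span:
        # |f - s| <= (5/384) max|f''''| h^4 with f'''' = A w^4 sin(.)
        omega = 2 * np.pi / 1000.0
        bound = 5.0 / 384.0 * 5.0 * omega**4 * 251.0**4
        assert err < bound

    def test_long_gap_flagged_unrecoverable(self):
        x = np.zeros(5000)
        rec = recording_from_x(x, events=[GazeEvent(1000, "BLINK_START"), GazeEvent(1900, "BLINK_END")])
        for ch in rec.channels().values():
            ch[1000:1901] = np.nan
        out = interpolate_blinks(rec, pad_ms=50, max_gap_ms=500)
        assert len(out.unrecoverable_gaps) == 1
        assert not np.isnan(out.left_x).any()

    def test_edge_blink_nearest_filled(self):
        x = np.arange(1000.0)
        rec = recording_from_x(x, events=[GazeEvent(0, "BLINK_START"), GazeEvent(80, "BLINK_END")])
        for ch in rec.channels().values():
            ch[:81] = np.nan
        out = interpolate_blinks(rec, pad_ms=50)
        assert not np.isnan(out.left_x).any()


class TestCalibrationFit:
    def make_calib_recording(self, gain=1.0, offset=0.0):
        from gazecraft.preprocess import CALIB_TARGETS

        chunks, events = [], []
        for i, (k, (tx, _)) in enumerate(sorted(CALIB_TARGETS.items())):
            events.append(GazeEvent(i * 1100, f"CALIB_POINT {k}"))
            chunks.append(np.full(1100, tx / gain + offset))
        x = np.concatenate(chunks)
        rec = recording_from_x(x)
        # vertical channel mirrors the y targets through the same affine
        y = np.concatenate(
            [np.full(1100, ty / gain + offset) for k, (_, ty) in sorted(CALIB_TARGETS.items())]
        )
        rec.left_y = y.copy()
        rec.right_y = y.copy()
        rec.events = events
        return rec

    def test_identity_when_medians_equal_targets(self):
        rec = self.make_calib_recording(gain=1.0, offset=0.0)
        cmap = fit_calibration(rec)
        assert cmap.gain_x == pytest.approx(1.0, abs=1e-12)
        assert cmap.offset_x == pytest.approx(0.0, abs=1e-9)

    def test_stimulus_centre_targets_map_to_plus_minus_100(self):
        rec = self.make_calib_recording(gain=0.05, offset=512.0)
        cmap = fit_calibration(rec)
        norm = normalize(rec, cmap)
        # fixation point segment maps to 0, left stimulus target to -100
        assert norm.left_x[0] == pytest.approx(0.0, abs=1e-9)       # point 1: centre
        assert norm.left_x[1100] == pytest.approx(-100.0, abs=1e-9)  # point 2: left
        assert norm.left_x[2200] == pytest.approx(100.0, abs=1e-9)   # point 3: right
    def test_degenerate_targets_rejected(self):
        rec = self.make_calib_recording()
        rec.events = [GazeEvent(e.time, "CALIB_POINT 1") for e in rec.events]
        with pytest.raises(IntegrityError, match="degenerate"):
            fit_calibration(rec)


class TestNormalize:
    def test_offset_maps_to_zero_and_inverts(self):
        cmap = CalibrationMap(gain_x=0.05, offset_x=512.0, gain_y=0.05, offset_y=512.0)
        rec = recording_from_x(np.full(10, 512.0))
        out = normalize(rec, cmap)
        np.testing.assert_allclose(out.left_x, 0.0, atol=1e-12)
        assert out.units == "normalized"
        np.testing.assert_allclose(cmap.invert_x(out.left_x), rec.left_x, atol=1e-12)

    def test_double_normalization_rejected(self):
        cmap = CalibrationMap(1.0, 0.0, 1.0, 0.0)
        rec = recording_from_x(np.zeros(10), units="normalized")
        with pytest.raises(IntegrityError, match="already normalized"):
            normalize(rec, cmap)


class TestEpoching:
    def make_session(self, n_trials=4, value=7.0):
        n = 3000 + n_trials * 2500
        rec = recording_from_x(np.full(n, value), units="normalized")
        trials = pd.DataFrame(
            {
                "trial_id": np.arange(n_trials),
                "experiment": 1,
                "condition": "sequential",
                "trial_subtype": "seq_left_first",
                "cued_side": ["left", "right"] * (n_trials // 2),
                "cue_onset": 3000 + np.arange(n_trials) * 2500,
                "target_orientation": 5.0,
                "reported_orientation": 10.0,
                "response_onset_ms": 250.0,
                "block": 0,
            }
        )
        return rec, trials

    def test_constant_channel_zero_after_baseline(self):
        rec, trials = self.make_session()
        epochs = epoch_and_baseline(rec, trials)
        assert epochs.n_trials == len(trials)
        np.testing.assert_allclose(epochs.data, 0.0, atol=1e-12)
        assert epochs.times[0] == -500 and epochs.times[-1] == 1499

    def test_baseline_mean_is_machine_zero_on_simulated_trials(self, clean_epochs):
        b = (clean_epochs.times >= -500) & (clean_epochs.times < 0)
        means = clean_epochs.data[:, b, :].mean(axis=1)
        assert np.abs(means).max() < 1e-12

    def test_edge_trial_dropped(self):
        rec, trials = self.make_session()
        trials.loc[0, "cue_onset"] = 100  # less than 500 ms history
        epochs = epoch_and_baseline(rec, trials)
        assert epochs.n_trials == len(trials) - 1


class TestExclusions:
    def test_gaze_excursion_trial_dropped_exactly(self):
        x = np.zeros((4, 2000))
        x[2, 900:1000] = 60.0  # 400-500 ms post-cue
        epochs = make_epochs(x)
        kept, report = exclude_trials(epochs)
        assert kept.n_trials == 3
        assert 2 not in kept.meta["trial_id"].to_numpy()
        assert report.to_frame()["n_excluded_gaze"].sum() == 1

    def test_pre_cue_excursion_not_penalized(self):
        x = np.zeros((2, 2000))
        x[0, 100:200] = 80.0  # during baseline, before cue
        kept, report = exclude_trials(make_epochs(x))
        assert kept.n_trials == 2

    def test_rt_outlier_dropped_iteratively_matches_hand_iteration(self):
        # hand iteration: pass 1 drops 10000 (mean 785, sd 2168, cut 9456);
        # pass 2 on the remainder drops 600 (mean 300, sd 0 over 300s... )
        rts = np.array([300.0] * 19 + [10000.0])
        kept, report = exclude_trials(make_epochs(np.zeros((20, 2000)), rts=rts))
        assert kept.n_trials == 19
        assert report.to_frame()["n_excluded_rt"].sum() == 1

        # second pass exposes a new outlier once the extreme one is removed
        rng = np.random.default_rng(0)
        base = rng.normal(300.0, 10.0, 30)
        rts2 = np.concatenate([base, [500.0, 50000.0]])
        mask = np.ones(rts2.size, bool)
        while True:  # independent hand iteration
            cut = rts2[mask].mean() + 4 * rts2[mask].std(ddof=1)
            new = mask & (rts2 > cut)
            if not new.any():
                break
            mask &= ~new
        kept2, _ = exclude_trials(make_epochs(np.zeros((rts2.size, 2000)), rts=rts2))
        assert kept2.n_trials == mask.sum()
        assert set(kept2.meta["trial_id"]) == set(np.flatnonzero(mask))

    def test_exclusion_is_idempotent(self, clean_epochs):
        once, _ = exclude_trials(clean_epochs)
        twice, rep = exclude_trials(once)
        assert twice.n_trials == once.n_trials
        assert rep.to_frame()[["n_excluded_gaze", "n_excluded_rt"]].to_numpy().sum() == 0

    def test_default_simulated_exclusion_rate_single_digit(self, small_session):
        from conftest import preprocess_session

        _, rec, trials, _ = small_session
        _, report = preprocess_session(rec, trials)
        f = report.to_frame()
        assert (f["pct_total"] <= 10.0).all()

    def test_all_excluded_raises(self):
        x = np.full((2, 2000), 90.0)
        x[:, :500] = 0.0  # post-cue excursion in every trial
        with pytest.raises(IntegrityError, match="all trials"):
            exclude_trials(make_epochs(x))
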