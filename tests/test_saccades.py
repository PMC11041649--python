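"""Detector behaviour, direction labels, rate and magnitude time courses."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_epochs
from gazecraft.gaze_io import IntegrityError
from gazecraft.saccades import (
    DEFAULT_MAG_EDGES,
    SaccadeParams,
    classify_direction,
    detect_saccades,
    magnitude_bias_map,
    rate_timecourses,
    score_detection,
)


def smoothstep(n):
    u = np.arange(1, n + 1) / n
    return 3 * u**2 - 2 * u**3


def epochs_with_step(dx=10.0, onset=1000, n_trials=1, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise, size=(n_trials, 2000))
    x[:, onset : onset + 20] += dx * smoothstep(20)
    x[:, onset + 20 :] += dx
    return make_epochs(x)


class TestDetect:
    def test_pure_noise_yields_no_events(self):
        rng = np.random.default_rng(1)
        epochs = make_epochs(rng.normal(0, 0.2, size=(20, 2000)))
        events = detect_saccades(epochs)
        assert len(events) == 0

    def test_single_step_detected_with_correct_displacement(self):
        events = detect_saccades(epochs_with_step(dx=10.0, noise=0.05))
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev["dx"] == pytest.approx(10.0, abs=0.5)
        assert abs(ev["onset_ms"] - 500) <= 5  # epoch time: onset sample 1000 -> +500 ms
        assert ev["magnitude"] > 1.0

    def test_min_magnitude_monotonicity(self, clean_epochs):
        lo = detect_saccades(clean_epochs, SaccadeParams(min_magnitude_units=0.5))
        hi = detect_saccades(clean_epochs, SaccadeParams(min_magnitude_units=2.0))
        assert len(lo) >= len(hi)

    def test_short_epoch_rejected(self):
        with pytest.raises(IntegrityError, match="velocity"):
            detect_saccades(make_epochs(np.zeros((1, 5))))

    def test_recall_and_onset_accuracy_against_ground_truth(self, clean_session, clean_epochs):
        _, _, trials, truth = clean_session
        events = detect_saccades(clean_epochs)
        kept = set(clean_epochs.meta["trial_id"])
        inj = truth.saccades[(truth.saccades["trial_id"] >= 0)]
        inj = inj[inj["trial_id"].isin(kept)]
        scored = score_detection(events, inj, tol_ms=20, min_amplitude=3.0)
        assert scored["matched"].mean() >= 0.95
        assert scored.loc[scored["matched"], "onset_error_ms"].abs().mean() <= 5.0


class TestClassify:
    @pytest.mark.parametrize(
        "dx,side,expected",
        [(5.0, "right", "toward"), (5.0, "left", "away"), (-5.0, "left", "toward")],
    )
    def test_direction_convention(self, dx, side, expected):
        epochs = make_epochs(np.zeros((1, 2000)), cued_sides=[side])
        events = pd.DataFrame(
            {
                "trial_id": [0],
                "onset_ms": [600],
                "offset_ms": [620],
                "dx": [dx],
                "magnitude": [abs(dx)],
                "peak_velocity": [300.0],
            }
        )
        out = classify_direction(events, epochs.meta)
        assert out["direction"].iloc[0] == expected

    def test_simulated_label_tallies_match_ground_truth(self, clean_session, clean_epochs):
        _, _, trials, truth = clean_session
        events = classify_direction(detect_saccades(clean_epochs), trials)
        kept = set(clean_epochs.meta["trial_id"])
        inj = truth.saccades[(truth.saccades["trial_id"].isin(kept))]
        scored = score_detection(events, inj, tol_ms=20, min_amplitude=3.0)
        truth_frac = (inj[inj["amplitude"] >= 3.0]["direction"] == "toward").mean()
        det_frac = (events["direction"] == "toward").mean()
        # detector recall > 95%, so detected label proportions track the truth
        assert det_frac == pytest.approx(truth_frac, abs=0.05)


class TestRates:
    def test_no_events_all_zero(self):
        epochs = make_epochs(np.zeros((5, 2000)))
        empty = pd.DataFrame(
            columns=["trial_id", "onset_ms", "offset_ms", "dx", "magnitude", "peak_velocity", "direction"]
        )
        rates = rate_timecourses(empty, epochs)
        assert np.all(rates.toward_hz == 0) and np.all(rates.away_hz == 0)

    def test_one_event_per_trial_gives_10_hz_plateau(self):
        n = 100
        epochs = make_epochs(np.zeros((n, 2000)), cued_sides=["right"] * n)
        events = pd.DataFrame(
            {
                "trial_id": np.arange(n),
                "onset_ms": 600,
                "offset_ms": 620,
                "dx": 5.0,
                "magnitude": 5.0,
                "peak_velocity": 300.0,
                "direction": "toward",
            }
        )
        rates = rate_timecourses(events, epochs, smooth_ms=100)
        # 1 onset/trial spread by the 100 ms moving average: 10 Hz in-window
        in_window = rates.toward_hz[np.abs(rates.times - 600) <= 40]
        np.testing.assert_allclose(in_window, 10.0, atol=1e-9)
        assert rates.toward_hz.max() == pytest.approx(10.0, abs=1e-9)
        np.testing.assert_array_equal(rates.away_hz, 0.0)

    def test_rate_integral_conserves_event_count(self, clean_session, clean_epochs):
        _, _, trials, _ = clean_session
        events = classify_direction(detect_saccades(clean_epochs), trials)
        rates = rate_timecourses(events, clean_epochs, smooth_ms=1)  # unsmoothed
        total = (rates.toward_hz + rates.away_hz).sum() / 1000.0
        assert total == pytest.approx(len(events) / clean_epochs.n_trials, rel=1e-9)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(6)
        n_trials, rate = 200, 2.0
        rows = []
        for t in range(n_trials):
            k = rng.poisson(rate * 2.0)  # 2 s epoch
            for on in rng.integers(-500, 1500, k):
                rows.append({"trial_id": t, "onset_ms": int(on), "offset_ms": int(on) + 20,
                             "dx": 5.0, "magnitude": 5.0, "peak_velocity": 300.0, "direction": "toward"})
        epochs = make_epochs(np.zeros((n_trials, 2000)), cued_sides=["right"] * n_trials)
        rates = rate_timecourses(pd.DataFrame(rows), epochs)
        est = rates.toward_hz.mean()
        se = np.sqrt(rate / (2.0 * n_trials))  # Poisson counting error on the mean rate
        assert abs(est - rate) < 3 * se

    def test_mirror_antisymmetry_of_effect(self):
        epochs = make_epochs(np.zeros((2, 2000)), cued_sides=["right", "left"])
        events = pd.DataFrame(
            {
                "trial_id": [0, 1],
                "onset_ms": [400, 700],
                "offset_ms": [420, 720],
                "dx": [5.0, 5.0],
                "magnitude": [5.0, 5.0],
                "peak_velocity": [300.0, 300.0],
            }
        )
        fwd = rate_timecourses(classify_direction(events, epochs.meta), epochs)
        mirrored = epochs.meta.copy()
        mirrored["cued_side"] = mirrored["cued_side"].map({"left": "right", "right": "left"})
        rev = rate_timecourses(classify_direction(events, mirrored), epochs)
        np.testing.assert_allclose(fwd.effect_hz, -rev.effect_hz, atol=1e-12)


class TestMagnitudeMap:
    def make_events(self, mags, n_trials=10):
        return pd.DataFrame(
            {
                "trial_id": np.arange(len(mags)) % n_trials,
                "onset_ms": 600,
                "offset_ms": 620,
                "dx": mags,
                "magnitude": np.abs(mags),
                "peak_velocity": 300.0,
                "direction": "toward",
            }
        )

    def test_bin_edges_follow_convention(self):
        assert DEFAULT_MAG_EDGES[0] == 2 and DEFAULT_MAG_EDGES[-1] == 110
        assert np.all(np.diff(DEFAULT_MAG_EDGES) == 4)

    def test_magnitude_5_falls_only_in_first_bin(self):
        n = 10
        epochs = make_epochs(np.zeros((n, 2000)), cued_sides=["right"] * n)
        events = self.make_events(np.full(n, 5.0), n)
        m = magnitude_bias_map(events, epochs)
        nonzero_bins = np.flatnonzero(np.abs(m.effect_hz).sum(axis=1) > 0)
        assert list(nonzero_bins) == [0]  # [2, 6)

    def test_summing_bins_reproduces_1d_effect(self, clean_session, clean_epochs):
        _, _, trials, _ = clean_session
        events = classify_direction(detect_saccades(clean_epochs), trials)
        in_range = events[(events["magnitude"] >= 2) & (events["magnitude"] < 110)]
        m = magnitude_bias_map(events, clean_epochs, smooth_ms=100)
        rates = rate_timecourses(in_range, clean_epochs, smooth_ms=100)
        np.testing.assert_allclose(m.effect_hz.sum(axis=0), rates.effect_hz, atol=1e-9)
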