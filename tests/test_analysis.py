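"""Analysis chain: merging, smoothing, two-stage averaging, direction folding."""

import numpy as np
import pandas as pd
import pytest

from flytread.analysis import (TrialTimeSeries, analyze_tuning, bar_profile,
                               combine_directions, condition_means, extract_trials,
                               merge_logs, per_fly_then_population, smooth_sliding,
                               trial_table, tuning_curve)
from flytread.engine import TransportModel, run_experiment
from flytread.fictrac import FicTracData
from flytread.geometry import DisplayGeometry
from flytread.simfly import FlyModel
from flytread.stimuli import build_protocol, randomize_blocks

GEOM = DisplayGeometry()


class TestSmoothing:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_sliding(np.full(20, 3.3), 5), 3.3,
                                   rtol=1e-15)

    def test_window_one_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(smooth_sliding(x, 1), x)

    def test_truncated_edges_worked_example(self):
        out = smooth_sliding([0, 0, 5, 0, 0], 5)
        np.testing.assert_allclose(out, [5 / 3, 5 / 4, 1.0, 5 / 4, 5 / 3])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_sliding(np.zeros(10), 4)

    def test_interior_mean_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        out = smooth_sliding(x, 5)
        # away from the truncated edges the window is full, so windowed sums telescope
        assert np.mean(out[2:-2]) == pytest.approx(
            np.mean(np.convolve(x, np.ones(5) / 5, "valid")), abs=1e-12)


@pytest.fixture(scope="module")
def run():
    proto = build_protocol("temporal", n_blocks=1, startup_delay_ms=1000.0)
    trials = randomize_blocks(proto, seed=3)
    fly = FlyModel(seed=1)
    return run_experiment(trials, GEOM, TransportModel(), fly,
                          startup_delay_ms=1000.0)


@pytest.fixture(scope="module")
def runs():
    proto = build_protocol("temporal", n_blocks=2, startup_delay_ms=1000.0)
    out = []
    for i in range(3):
        trials = randomize_blocks(proto, seed=10 + i)
        fly = FlyModel(seed=20 + i, motor_noise_sd_dps=10.0)
        out.append(run_experiment(trials, GEOM, TransportModel(seed=i), fly,
                                  startup_delay_ms=1000.0))
    return out


class TestMergeAndEpochs:
    def test_all_trials_present(self, run):
        merged = merge_logs(run.event_log, run.fictrac)
        labeled = merged.loc[merged["trial_index"] >= 0, "trial_index"]
        assert labeled.nunique() == 15  # 14 open loop + 1 closed loop

    def test_motion_onset_is_half_open(self, run):
        merged = merge_logs(run.event_log, run.fictrac)
        tt = trial_table(run.event_log)
        for _, tr in tt.head(3).iterrows():
            rows = merged[merged["trial_index"] == tr["trial_index"]]
            in_motion = rows[rows["epoch"] == "motion"]
            assert in_motion["t_s"].min() >= tr["t_motion_on_s"]
            assert in_motion["t_s"].max() < tr["t_motion_off_s"]

    def test_frames_inside_motion_epoch_labeled(self, run):
        merged = merge_logs(run.event_log, run.fictrac)
        tt = trial_table(run.event_log)
        tr = tt.iloc[0]
        mid = (tr["t_motion_on_s"] + tr["t_motion_off_s"]) / 2
        row = merged.iloc[(merged["t_s"] - mid).abs().argmin()]
        assert row["epoch"] == "motion"
        assert row["condition_id"] == tr["condition_id"]

    def test_non_overlapping_streams_rejected(self, run):
        late = FicTracData.from_components(
            np.zeros(10), np.zeros(10), np.full(10, 10_000.0))
        with pytest.raises(ValueError, match="overlap"):
            merge_logs(run.event_log, late)

    def test_closed_loop_excluded_by_count(self, run):
        merged = merge_logs(run.event_log, run.fictrac)
        trials = extract_trials(merged)
        assert len(trials) == 14  # the closed-loop trial is dropped
        with_cl = extract_trials(merged, include_closed_loop=True)
        assert len(with_cl) == 15


def _flat_trial(fly, value, condition="c", direction="cw", n=60, param=1.0):
    t = np.arange(n) / 180.0 - 0.1
    return TrialTimeSeries(fly, 0, condition, "grating", param, direction,
                           t, np.full(n, float(value)), motion_s=t[-1] + 1 / 180,
                           pre_s=0.1)


class TestAveraging:
    def test_single_fly_identical_trials_returns_the_trial(self):
        trials = [_flat_trial(0, 7.0) for _ in range(4)]
        pop = per_fly_then_population(trials)
        np.testing.assert_allclose(pop["mean_dps"], 7.0)

    def test_opposite_flies_average_to_zero(self):
        pop = per_fly_then_population([_flat_trial(0, 10.0), _flat_trial(1, -10.0)])
        np.testing.assert_allclose(pop["mean_dps"], 0.0, atol=1e-12)
        assert pop["n_flies"].max() == 2

    def test_flies_weighted_equally_regardless_of_trial_count(self):
        """Two-stage averaging: 6 trials of fly A count as much as 3 of fly B."""
        trials = ([_flat_trial(0, 6.0) for _ in range(6)]
                  + [_flat_trial(1, 12.0) for _ in range(3)])
        pop = per_fly_then_population(trials)
        np.testing.assert_allclose(pop["mean_dps"], 9.0)  # pooled would give 8.0

    def test_condition_means_use_motion_epoch_only(self):
        n = 90
        t = np.arange(n) / 180.0 - 0.1
        yaw = np.where((t >= 0) & (t < 0.3), 50.0, -999.0)
        tr = TrialTimeSeries(0, 0, "c", "grating", 1.0, "cw", t, yaw,
                             motion_s=0.3, pre_s=0.1)
        means = condition_means([tr])
        assert means["value"].iloc[0] == pytest.approx(50.0)


class TestCombineDirections:
    def test_perfect_antisymmetry_preserved(self):
        assert combine_directions(50.0, -50.0) == 50.0

    def test_pure_bias_cancels(self):
        assert combine_directions(7.0, 7.0) == 0.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            combine_directions(np.zeros(5), np.zeros(6))

    def test_injected_turning_bias_cancels_in_simulation(self):
        """A direction-independent turning bias b drops out of the combined curve."""
        rng = np.random.default_rng(0)
        base = rng.normal(20.0, 5.0, 200)
        for bias in (0.0, 15.0):
            cw = base + bias
            ccw = -base + bias
            np.testing.assert_allclose(combine_directions(cw, ccw), base, atol=1e-12)


class TestTuningCurve:
    def test_noise_free_mean_and_zero_sem(self):
        df = pd.DataFrame({"fly_id": [0, 1, 2], "param": 4.0, "value": 30.0})
        curve = tuning_curve(df)
        assert curve.mean_dps[0] == pytest.approx(30.0)
        assert curve.sem_dps[0] == pytest.approx(0.0)
        assert curve.n_flies == 3

    def test_sem_flagged_undefined_for_single_fly(self):
        df = pd.DataFrame({"fly_id": [0], "param": [4.0], "value": [30.0]})
        assert np.isnan(tuning_curve(df).sem_dps[0])

    def test_sem_matches_sd_over_sqrt_n(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        df = pd.DataFrame({"fly_id": range(4), "param": 1.0, "value": vals})
        curve = tuning_curve(df)
        assert curve.sem_dps[0] == pytest.approx(np.std(vals, ddof=1) / 2.0)


class TestEndToEnd:
    def test_negated_headings_negate_tuning_exactly(self, runs):
        res = analyze_tuning(runs, compute_traces=False)
        mirrored = []
        for r in runs:
            neg = FicTracData.from_components(
                np.mod(-r.fictrac.heading_rad, 2 * np.pi),
                r.fictrac.movement_speed_rad_per_frame,
                r.fictrac.delta_timestamp_s)
            mirrored.append((r.event_log, neg))
        res_m = analyze_tuning(mirrored, compute_traces=False)
        np.testing.assert_allclose(res_m.tuning.mean_dps, -res.tuning.mean_dps,
                                   atol=1e-9)

    def test_closed_loop_exclusion_counted(self, runs):
        res = analyze_tuning(runs, compute_traces=False)
        assert res.n_closed_loop_excluded == 3 * 2  # one per block per fly

    def test_forward_speed_near_configured_mean(self, runs):
        res = analyze_tuning(runs, compute_traces=False)
        assert res.mean_forward_speed_mm_s == pytest.approx(10.0, abs=0.3)


class TestBarProfile:
    def test_crossing_time_kinematics(self):
        """At 90 deg/s the bar crosses the midline at (span/2)/omega = 0.975 s."""
        n = int(7.8 * 180)
        t = np.arange(n) / 180.0
        tr = TrialTimeSeries(0, 0, "bar-90", "bar", 90.0, "cw", t,
                             np.zeros(n), motion_s=175.5 / 90.0, pre_s=0.0)
        prof = bar_profile([tr])[0]
        cross = prof.t_s[np.nanargmin(np.abs(prof.bar_azimuth_deg))]
        assert cross == pytest.approx((175.5 / 2) / 90.0, abs=0.01)

    def test_ccw_folds_onto_cw_with_sign_flip(self):
        n = 200
        t = np.arange(n) / 180.0
        yaw = np.sin(t * 3.0) * 30.0
        cw = TrialTimeSeries(0, 0, "b", "bar", 360.0, "cw", t, yaw,
                             motion_s=175.5 / 360.0, pre_s=0.0)
        ccw = TrialTimeSeries(0, 1, "b", "bar", 360.0, "ccw", t, -yaw,
                              motion_s=175.5 / 360.0, pre_s=0.0)
        prof = bar_profile([cw, ccw])[0]
        np.testing.assert_allclose(prof.mean_dps, yaw, atol=1e-9)

    def test_zero_gain_fly_flat_profile(self):
        n = 100
        t = np.arange(n) / 180.0
        tr = TrialTimeSeries(0, 0, "b", "bar", 90.0, "cw", t, np.zeros(n),
                             motion_s=0.5, pre_s=0.0)
        prof = bar_profile([tr])[0]
        np.testing.assert_allclose(prof.mean_dps, 0.0)

    def test_requires_bar_trials(self):
        with pytest.raises(ValueError):
            bar_profile([_flat_trial(0, 1.0)])
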