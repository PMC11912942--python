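"""Initial-contact detection, outlier strides, 101-point time normalization."""

import numpy as np
import pytest

from ccigait import (
    PHASE_GRID,
    TrialCondition,
    UnsegmentableTrialError,
    build_stride_matrix,
    config_variant,
    detect_initial_contacts,
    flag_stride_outliers,
    make_stride_set,
    simulate_trial,
)
from ccigait.emg import EnvelopeTrial
from ccigait.synthetic import SimulationConfig, evaluate_profiles, make_activation_profile


def _envelope_trial_from(envelopes, rate):
    return EnvelopeTrial(
        trial_id="t0",
        participant_id="TD01",
        limb="left",
        population="TD",
        environment="Dry",
        speed="Normal",
        envelopes=envelopes,
        rate_hz=rate,
    )


class TestDetectInitialContacts:
    def test_noiseless_trace_recovered_within_one_sample(self, dry_normal_condition):
        config = config_variant(
            SimulationConfig(), strides_per_trial=10, accel_noise_sd_g=0.0, noise_sd=0.0
        )
        trial = simulate_trial(config, dry_normal_condition, 3)
        detected = detect_initial_contacts(
            trial.accel_vertical, trial.imu_rate_hz, config.stride_time_mean_s
        )
        true = trial.true_initial_contacts_s
        assert len(detected) == len(true)
        assert np.max(np.abs(detected - true)) <= 1.0 / trial.imu_rate_hz

    def test_flat_signal_is_unsegmentable(self):
        with pytest.raises(UnsegmentableTrialError):
            detect_initial_contacts(np.zeros(1000), 142.0, 1.0)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            detect_initial_contacts(np.ones(100), -1.0, 1.0)


class TestFlagStrideOutliers:
    def test_equal_durations_produce_no_flags(self):
        assert not flag_stride_outliers(np.ones(10)).any()

    def test_single_doubled_stride_is_the_only_flag(self):
        # 50 strides of 1.000 s plus one of 2.000 s: mean ~1.0196, SD ~0.140,
        # 3-SD band ~0.42 around the mean, so only the 2 s stride is out
        durations = np.array([1.0] * 50 + [2.0])
        flags = flag_stride_outliers(durations)
        assert flags.sum() == 1 and flags[-1]

    def test_moderate_deviation_is_not_flagged(self):
        # deviation of the 5 s stride is 1.79 sample SDs: retained
        assert not flag_stride_outliers(np.array([1.0, 1.0, 1.0, 1.0, 5.0])).any()

    def test_fewer_than_three_strides_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            flag_stride_outliers(np.array([1.0, 1.0]))


class TestBuildStrideMatrix:
    def _constant_trial(self, value, rate=200.0, n=4000):
        env = {m: np.full(n, value) for m in ("TA", "MG", "RF", "ST")}
        return _envelope_trial_from(env, rate)

    def test_constant_envelope_gives_constant_rows(self):
        trial = self._constant_trial(0.3)
        strides = make_stride_set(np.array([1.0, 2.0, 3.1, 4.1, 5.2]))
        matrix = build_stride_matrix(trial, strides, "TA/MG")
        assert matrix.muscle_1.shape == (4, 101)
        np.testing.assert_allclose(matrix.muscle_1, 0.3)
        np.testing.assert_allclose(matrix.muscle_2, 0.3)

    def test_linear_envelope_maps_to_linear_phase_rows(self):
        rate, n = 500.0, 3000
        t = np.arange(n) / rate
        env = {m: 2.0 * t for m in ("TA", "MG", "RF", "ST")}
        trial = _envelope_trial_from(env, rate)
        strides = make_stride_set(np.array([1.0, 2.0, 3.0, 4.0]))
        matrix = build_stride_matrix(trial, strides, "RF/ST")
        row = matrix.muscle_1[0]
        expected = 2.0 * np.linspace(1.0, 2.0, 101)
        np.testing.assert_allclose(row, expected, rtol=1e-6)
        assert row[0] == pytest.approx(2.0) and row[-1] == pytest.approx(4.0)

    def test_bandlimited_profile_roundtrip_error_below_one_percent(
        self, dry_normal_condition
    ):
        # sample a smooth profile at EMG rate, interpolate to the phase grid,
        # compare against the analytic values on that grid
        config = SimulationConfig()
        rate = 2000.0
        profile = make_activation_profile("MG", config, dry_normal_condition)
        ics = np.array([0.0, 1.1, 2.2, 3.3])
        t = np.arange(int(3.3 * rate) + 1) / rate
        idx = np.clip(np.searchsorted(ics, t, side="right") - 1, 0, 2)
        phase = (t - ics[idx]) / 1.1
        env = {m: profile(phase) for m in ("TA", "MG", "RF", "ST")}
        trial = _envelope_trial_from(env, rate)
        matrix = build_stride_matrix(trial, make_stride_set(ics), "TA/MG")
        expected = profile(PHASE_GRID / 100.0)
        scale = expected.max() - expected.min()
        for row in matrix.muscle_2:
            assert np.max(np.abs(row - expected)) < 0.01 * scale

    def test_unknown_pairing_rejected(self):
        trial = self._constant_trial(0.2)
        strides = make_stride_set(np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="unknown pairing"):
            build_stride_matrix(trial, strides, "TA/ST")

    def test_out_of_recording_strides_dropped(self):
        trial = self._constant_trial(0.5, rate=200.0, n=1000)  # 5 s recording
        strides = make_stride_set(np.array([1.0, 2.0, 3.0, 4.0, 6.0]))
        matrix = build_stride_matrix(trial, strides, "TA/MG")
        assert list(matrix.stride_ids) == [0, 1, 2]

    def test_outlier_removal_leaves_retained_rows_unchanged(self):
        rng = np.random.default_rng(4)
        rate, n = 100.0, 2500
        env = {m: rng.random(n) for m in ("TA", "MG", "RF", "ST")}
        trial = _envelope_trial_from(env, rate)
        # twelve 1 s strides and one 6 s stride (4.6 sample SDs out: flagged)
        ics = np.concatenate([np.arange(1.0, 14.0), [19.0]])
        full = make_stride_set(ics)
        assert full.outlier_flags.any()
        matrix = build_stride_matrix(trial, full, "RF/ST")
        # rebuild from only the retained contacts: identical rows
        for k, i in enumerate(full.retained_stride_indices):
            t0, t1 = ics[i], ics[i + 1]
            grid = np.linspace(t0, t1, 101)
            expected = np.interp(grid, np.arange(n) / rate, env["RF"])
            np.testing.assert_array_equal(matrix.muscle_1[k], expected)

    def test_segmentation_recovers_generating_profile(self, dry_normal_condition):
        """Noise-free pipeline: segmentation + interpolation reproduce the
        activation profile on the phase grid within 2% RMS."""
        config = config_variant(SimulationConfig(), strides_per_trial=6)
        ics = 0.1 + np.concatenate([[0.0], np.cumsum([1.0, 1.1, 0.95, 1.05, 1.0, 1.12])])
        rate = 2000.0
        profiles = evaluate_profiles(
            config, dry_normal_condition, ics, rate, t_end=ics[-1] + 0.05
        )
        trial = _envelope_trial_from(profiles, rate)
        matrix = build_stride_matrix(trial, make_stride_set(ics), "TA/MG")
        expected = make_activation_profile("TA", config, dry_normal_condition)(
            PHASE_GRID / 100.0
        )
        for row in matrix.muscle_1:
            rms = np.sqrt(np.mean((row - expected) ** 2))
            assert rms < 0.02 * np.sqrt(np.mean(expected**2)) + 1e-9
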