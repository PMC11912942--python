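"""Co-contraction formulas: closed forms, invariants, trial aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ccigait import (
    PHASE_GRID,
    SimulationConfig,
    TrialCondition,
    cci_falconer_winter,
    cci_rudolph,
    cci_trial,
    cci_unnithan,
    config_variant,
    make_activation_profile,
)
from ccigait.cci import MusclePairSeries
from ccigait.segmentation import StrideMatrix

N = 101
envelopes = hnp.arrays(
    dtype=float,
    shape=N,
    # zero or well away from underflow, as real envelopes are
    elements=st.floats(0.0, 10.0, allow_nan=False).map(
        lambda v: 0.0 if v < 1e-6 else v
    ),
)


def _matrix(rows_1, rows_2, pairing="RF/ST"):
    return StrideMatrix(
        pairing=pairing,
        muscles=("RF", "ST"),
        muscle_1=np.asarray(rows_1, dtype=float),
        muscle_2=np.asarray(rows_2, dtype=float),
        stride_ids=np.arange(len(rows_1)),
    )


class TestClosedForms:
    def test_unnithan_constant_pair(self):
        # min is 0.2 on the whole 0-100 axis
        assert cci_unnithan(np.full(N, 0.2), np.full(N, 0.5)) == pytest.approx(20.0)

    def test_unnithan_disjoint_supports_is_zero(self):
        a = np.zeros(N)
        a[:50] = 1.0
        b = np.zeros(N)
        b[50:] = 1.0
        b[50] = 0.0
        assert cci_unnithan(a, b) == 0.0

    def test_unnithan_crossing_ramps(self):
        # ramps 0->1 and 1->0 cross exactly at the 50% grid point, where the
        # min is piecewise linear: the trapezoid is exact at 25.0
        up = np.linspace(0, 1, N)
        down = np.linspace(1, 0, N)
        assert cci_unnithan(up, down) == pytest.approx(25.0, abs=1e-9)
        # independent fine-grid Riemann oracle on the continuous ramps
        x = (np.arange(100_000) + 0.5) / 100_000
        oracle = np.minimum(x, 1 - x).mean() * 100.0
        assert cci_unnithan(up, down) == pytest.approx(oracle, rel=0.01)

    def test_rudolph_equal_constant_pair(self):
        assert cci_rudolph(np.full(N, 0.25), np.full(N, 0.25)) == pytest.approx(0.5)

    def test_rudolph_zero_series_is_zero(self):
        assert cci_rudolph(np.zeros(N), np.full(N, 0.4)) == 0.0

    def test_rudolph_hand_arithmetic(self):
        # (0.1/0.3) * 0.4 = 0.13333...
        assert cci_rudolph(np.full(N, 0.1), np.full(N, 0.3)) == pytest.approx(0.4 / 3)

    def test_fw_equal_split_is_100(self):
        assert cci_falconer_winter(np.full(N, 0.7), np.full(N, 0.7)) == pytest.approx(100.0)

    def test_fw_pure_antagonist_is_200(self):
        assert cci_falconer_winter(np.full(N, 0.3), np.zeros(N)) == pytest.approx(200.0)

    def test_fw_silent_antagonist_is_0(self):
        assert cci_falconer_winter(np.zeros(N), np.full(N, 0.3)) == pytest.approx(0.0)

    def test_zero_policy_drop(self):
        a = np.zeros(N)
        a[:10] = 0.2
        b = np.zeros(N)
        b[:10] = 0.2
        assert cci_rudolph(a, b, zero_policy="drop") == pytest.approx(0.4)
        assert cci_falconer_winter(a, b, zero_policy="drop") == pytest.approx(100.0)


class TestInvariants:
    @settings(max_examples=50, derandomize=True)
    @given(envelopes, envelopes)
    def test_unnithan_symmetric_and_bounded(self, a, b):
        phase = np.linspace(0.0, 100.0, N)
        value = cci_unnithan(a, b)
        assert value == pytest.approx(cci_unnithan(b, a), rel=1e-12, abs=1e-12)
        bound = min(np.trapezoid(a, phase), np.trapezoid(b, phase))
        assert value <= bound + 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(envelopes, envelopes)
    def test_rudolph_per_sample_bounded_by_total(self, a, b):
        small, large = np.minimum(a, b), np.maximum(a, b)
        active = large > 0
        per_sample = np.zeros(N)
        np.divide(small, large, out=per_sample, where=active)
        per_sample *= small + large
        assert np.all(per_sample <= 2 * small + 1e-9)
        assert np.all(per_sample <= a + b + 1e-9)
        assert cci_rudolph(a, b) >= 0

    @settings(max_examples=50, derandomize=True)
    @given(envelopes, envelopes)
    def test_fw_within_0_200(self, a, b):
        assert 0.0 <= cci_falconer_winter(a, b) <= 200.0

    @settings(max_examples=30, derandomize=True)
    @given(envelopes, envelopes, st.floats(0.1, 50.0))
    def test_scaling_behaviour(self, a, b, c):
        assert cci_unnithan(c * a, c * b) == pytest.approx(c * cci_unnithan(a, b), rel=1e-9)
        assert cci_rudolph(c * a, c * b) == pytest.approx(c * cci_rudolph(a, b), rel=1e-9)
        assert cci_falconer_winter(c * a, c * b) == pytest.approx(
            cci_falconer_winter(a, b), rel=1e-9, abs=1e-9
        )

    def test_trapezoid_matches_fine_riemann_on_bandlimited_profiles(self):
        """101-point trapezoid vs 1e5-point Riemann on simulator waveforms."""
        config = SimulationConfig()
        cond = TrialCondition("TD01", "left", "TD", "Dry", "Normal")
        fine = (np.arange(100_000) + 0.5) / 100_000
        for m1, m2 in (("RF", "ST"), ("TA", "MG")):
            p1 = make_activation_profile(m1, config, cond)
            p2 = make_activation_profile(m2, config, cond)
            coarse = cci_unnithan(p1(PHASE_GRID / 100), p2(PHASE_GRID / 100))
            oracle = np.minimum(p1(fine), p2(fine)).mean() * 100.0
            assert coarse == pytest.approx(oracle, rel=0.01)


class TestMusclePairSeries:
    def test_small_large_roles(self):
        pair = MusclePairSeries(emg_1=np.full(N, 0.4), emg_2=np.full(N, 0.1))
        np.testing.assert_allclose(pair.emg_small, 0.1)
        np.testing.assert_allclose(pair.emg_large, 0.4)
        np.testing.assert_allclose(pair.emg_total, 0.5)
        np.testing.assert_allclose(pair.emg_antagonist, 0.4)

    def test_negative_activation_rejected(self):
        with pytest.raises(ValueError):
            MusclePairSeries(emg_1=np.full(N, -0.1), emg_2=np.zeros(N))


class TestCCITrial:
    def test_identical_strides_average_to_single_value(self):
        row = np.full(N, 0.2)
        matrix = _matrix([row] * 3, [np.full(N, 0.5)] * 3)
        result = cci_trial(matrix, "unnithan")
        assert result.trial_value == pytest.approx(20.0)
        assert result.n_strides == 3

    def test_trial_value_is_mean_of_strides(self):
        rows_1 = [np.full(N, v) for v in (0.10, 0.20, 0.30)]
        rows_2 = [np.full(N, 1.0)] * 3
        result = cci_trial(_matrix(rows_1, rows_2), "unnithan")
        np.testing.assert_allclose(result.per_stride, [10.0, 20.0, 30.0])
        assert result.trial_value == pytest.approx(20.0)

    def test_default_antagonist_is_rf_and_ta(self):
        ant_rows = [np.full(N, 0.4)]
        ago_rows = [np.zeros(N)]
        result = cci_trial(_matrix(ant_rows, ago_rows), "fw")
        assert result.antagonist == "RF"
        assert result.trial_value == pytest.approx(200.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            cci_trial(_matrix([np.zeros(N)], [np.zeros(N)]), "ikeda")

    def test_cp_cohort_exceeds_td_cohort(self):
        """Elevated CP co-activation baseline orders mean Unnithan CCI CP > TD."""
        from ccigait import analyze_cohort, simulate_cohort

        config = config_variant(
            SimulationConfig(),
            n_participants_td=3,
            n_participants_cp=3,
            limbs=("left",),
            strides_per_trial=10,
            seed=31,
        )
        df = analyze_cohort(
            simulate_cohort(config), methods=("unnithan",), pairings=("RF/ST",)
        )
        means = df.groupby("population")["trial_value"].mean()
        assert means["CP"] > means["TD"]
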