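"""Convolution, decay and AIF-splitting primitives against closed forms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxykin import (
    FrameSchedule,
    FrameTAC,
    SampledCurve,
    build_aif_set,
    decay_convert,
    expconv,
    frame_average,
    interpolate_lv_tac,
    metabolized_water_curve,
    oxygen_aif,
)
from oxykin.kinetics import O15_LAMBDA_PER_MIN


class TestExpconv:
    def test_zero_input_stays_zero(self, fine_grid):
        out = expconv(SampledCurve(fine_grid, np.zeros_like(fine_grid)), 2.0)
        assert np.all(out.values == 0.0)

    @pytest.mark.parametrize("rate", [0.33, 1.0, 5.0])
    def test_step_input_closed_form(self, step_curve, rate):
        out = expconv(step_curve, rate)
        exact = (1.0 - np.exp(-rate * step_curve.times)) / rate
        # piecewise-linear scheme is exact for a constant input
        np.testing.assert_allclose(out.values, exact, atol=1e-12)

    def test_step_value_at_unit_time_unit_rate(self, step_curve):
        out = expconv(step_curve, 1.0)
        assert np.interp(1.0, out.times, out.values) == pytest.approx(
            1.0 - np.exp(-1.0), abs=1e-12
        )

    @pytest.mark.parametrize("a,k", [(0.7, 1.3), (0.2, 2.5)])
    def test_exponential_input_closed_form(self, fine_grid, a, k):
        out = expconv(SampledCurve(fine_grid, np.exp(-a * fine_grid)), k)
        exact = (np.exp(-a * fine_grid) - np.exp(-k * fine_grid)) / (k - a)
        # exponential input is not piecewise linear: discretization error only
        np.testing.assert_allclose(out.values[1:], exact[1:], rtol=1e-3)

    def test_nonuniform_grid_matches_uniform(self):
        # same piecewise-linear curve sampled on two grids -> same integral
        t_u = np.linspace(0.0, 6.0, 361)
        rng = np.random.default_rng(0)
        t_n = np.unique(np.concatenate([[0.0, 6.0], rng.uniform(0, 6, 200)]))
        y = lambda t: np.interp(t, [0, 1, 3, 6], [0, 4, 1, 2])
        out_u = expconv(SampledCurve(t_u, y(t_u)), 0.8)
        out_n = expconv(SampledCurve(t_n, y(t_n)), 0.8)
        common = np.array([1.0, 2.0, 3.0, 4.5, 6.0])
        np.testing.assert_allclose(out_u(common), out_n(common), rtol=2e-3)

    def test_negative_rate_rejected(self, step_curve):
        with pytest.raises(ValueError):
            expconv(step_curve, -0.1)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            expconv(SampledCurve([0.0], [1.0]), 1.0)


class TestMetabolizedWater:
    def test_zero_kw_means_no_metabolism(self, ramp_curve):
        out = metabolized_water_curve(ramp_curve, 0.0)
        assert np.all(out.values == 0.0)

    def test_constant_total_saturates(self, fine_grid):
        a0, kw = 50.0, 0.33
        total = SampledCurve(fine_grid, np.full_like(fine_grid, a0))
        out = metabolized_water_curve(total, kw)
        exact = a0 * (1.0 - np.exp(-kw * fine_grid))
        np.testing.assert_allclose(out.values, exact, atol=1e-9)
        assert out.values[-1] < a0  # approaches but never exceeds the total

    def test_ramp_total_closed_form(self, ramp_curve):
        kw, c = 0.33, 2.0
        out = metabolized_water_curve(ramp_curve, kw)
        t = ramp_curve.times
        exact = c * t - (c / kw) * (1.0 - np.exp(-kw * t))
        np.testing.assert_allclose(out.values, exact, atol=1e-10)

    @given(kw_lo=st.floats(0.05, 1.0), bump=st.floats(0.01, 1.0))
    def test_monotone_in_kw_for_nondecreasing_total(self, kw_lo, bump):
        t = np.linspace(0.0, 8.0, 481)
        total = SampledCurve(t, 10.0 * (1.0 - np.exp(-t / 2.0)))
        lo = metabolized_water_curve(total, kw_lo)
        hi = metabolized_water_curve(total, kw_lo + bump)
        assert np.all(hi.values >= lo.values - 1e-9)


class TestAifSplit:
    def test_zero_water_identity(self, ramp_curve, fine_grid):
        zero = SampledCurve(fine_grid, np.zeros_like(fine_grid))
        out = oxygen_aif(ramp_curve, zero)
        np.testing.assert_array_equal(out.values, ramp_curve.values)

    def test_total_equals_water_gives_zero_oxygen(self, ramp_curve):
        out = oxygen_aif(ramp_curve, ramp_curve)
        assert np.all(out.values == 0.0)

    def test_grid_mismatch_rejected(self, ramp_curve):
        other = SampledCurve([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            oxygen_aif(ramp_curve, other)

    def test_ramp_total_oxygen_plateaus(self, ramp_curve):
        # for A_t = c t the oxygen AIF saturates at c / kw
        kw, c = 0.33, 2.0
        aifs = build_aif_set(ramp_curve, kw)
        t = ramp_curve.times
        exact = (c / kw) * (1.0 - np.exp(-kw * t))
        np.testing.assert_allclose(aifs.oxygen.values, exact, atol=1e-9)
        assert aifs.oxygen.values[-1] == pytest.approx(c / kw, rel=0.05)

    @pytest.mark.parametrize("kw", [0.1, 0.33, 1.0])
    def test_conservation(self, ramp_curve, kw):
        aifs = build_aif_set(ramp_curve, kw)
        resid = aifs.total.values - (aifs.water.values + aifs.oxygen.values)
        assert np.max(np.abs(resid)) < 1e-10


class TestDecayConvert:
    def test_wrong_direction_is_state_error(self):
        tac = FrameTAC(FrameSchedule([0.0], [1.0]), [5.0], decay_corrected=True)
        with pytest.raises(ValueError):
            decay_convert(tac, "to-corrected")

    def test_frame_mean_factor_is_exact_integral(self):
        lam = O15_LAMBDA_PER_MIN
        a0 = 10.0
        tac = FrameTAC(FrameSchedule([0.0], [1.0]), [a0], decay_corrected=True)
        out = decay_convert(tac, "to-uncorrected", lam)
        assert out.activities[0] == pytest.approx(a0 * (1 - np.exp(-lam)) / lam, rel=1e-12)
        assert not out.decay_corrected

    def test_round_trip_identity(self):
        sched = FrameSchedule.from_durations([5.0] * 12 + [15.0] * 8 + [30.0] * 6)
        rng = np.random.default_rng(1)
        tac = FrameTAC(sched, rng.uniform(1, 100, sched.n_frames), decay_corrected=True)
        back = decay_convert(decay_convert(tac, "to-uncorrected"), "to-corrected")
        np.testing.assert_allclose(back.activities, tac.activities, rtol=1e-12)

    def test_sampled_curve_pointwise(self, fine_grid):
        lam = 0.3402
        curve = SampledCurve(fine_grid, np.full_like(fine_grid, 4.0))
        out = decay_convert(curve, "to-uncorrected", lam)
        np.testing.assert_allclose(out.values, 4.0 * np.exp(-lam * fine_grid), rtol=1e-12)


class TestLvInterpolation:
    def test_constant_tac_gives_constant_curve(self):
        sched = FrameSchedule.uniform(4.0, 1.0)
        curve = interpolate_lv_tac(FrameTAC(sched, [7.0] * 4))
        q = np.linspace(0.0, 4.0, 41)
        np.testing.assert_array_equal(curve(q), np.full_like(q, 7.0))

    def test_midpoint_nodes_reproduced_and_linear_between(self):
        sched = FrameSchedule([0.0, 1.0], [1.0, 2.0])
        curve = interpolate_lv_tac(FrameTAC(sched, [1.0, 3.0]))
        assert curve(0.5) == 1.0 and curve(1.5) == 3.0
        assert curve(1.0) == pytest.approx(2.0)

    def test_zero_anchor_prepended_for_rising_activity(self):
        sched = FrameSchedule([0.0, 1.0], [1.0, 2.0])
        curve = interpolate_lv_tac(FrameTAC(sched, [1.0, 3.0]))
        assert curve(0.0) == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            interpolate_lv_tac(FrameTAC(FrameSchedule([0.0], [1.0]), [1.0]))


class TestFrameAverage:
    def test_constant_curve(self, step_curve):
        sched = FrameSchedule.uniform(6.0, 0.5)
        out = frame_average(step_curve, sched)
        np.testing.assert_allclose(out.activities, 1.0, rtol=1e-12)

    def test_linear_curve_gives_midpoint_value(self, ramp_curve):
        sched = FrameSchedule.from_durations([5.0] * 12 + [30.0] * 6)
        out = frame_average(ramp_curve, sched)
        np.testing.assert_allclose(out.activities, 2.0 * sched.midpoints, rtol=1e-10)

    def test_piecewise_linear_frames_exact(self):
        # kinks aligned with frame edges: trapezoid sub-quadrature is exact
        sched = FrameSchedule.uniform(3.0, 1.0)
        curve = SampledCurve([0.0, 1.0, 2.0, 3.0], [0.0, 4.0, 2.0, 6.0])
        out = frame_average(curve, sched)
        np.testing.assert_allclose(out.activities, [2.0, 3.0, 4.0], rtol=1e-12)

    def test_schedule_beyond_support_rejected(self, step_curve):
        with pytest.raises(ValueError):
            frame_average(step_curve, FrameSchedule.uniform(12.0, 1.0))


class TestScheduleInvariants:
    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule([0.0, 0.5], [1.0, 1.5])

    def test_protocol_schedule_spans_six_minutes(self):
        sched = FrameSchedule.from_durations([5.0] * 12 + [15.0] * 8 + [30.0] * 6)
        assert sched.span == (0.0, 6.0)
        assert sched.n_frames == 26
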