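"""Cycle slopes, MO2 computation and the SMR/MMR/MS/Q10 metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaresp import synthetic as sy
from aquaresp import whole_animal as wa
from aquaresp.traces import InsufficientDataError, OxygenTrace, RespirometrySetup


def _measure_trace(t, o2):
    return OxygenTrace(t, o2, 21.0, np.full(len(t), "measure", dtype=object))


class TestCycleSlopes:
    def test_exact_line_recovers_slope_and_unit_r2(self):
        t = np.arange(0.0, 300.0, 5.0)
        tr = _measure_trace(t, 100.0 - (2.0 / 60.0) * t)
        (c,) = wa.extract_cycle_slopes(tr)
        assert c.slope == pytest.approx(-120.0, rel=1e-12)
        assert c.r2 == pytest.approx(1.0)
        assert c.quality_ok

    def test_flat_segment_gives_zero_slope_flagged(self):
        t = np.arange(0.0, 300.0, 5.0)
        (c,) = wa.extract_cycle_slopes(_measure_trace(t, np.full(len(t), 90.0)))
        assert c.slope == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(c.r2)
        assert not c.quality_ok

    def test_noisy_line_matches_closed_form_ols(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 300.0, 5.0)
        y = 100.0 - (2.0 / 60.0) * t + rng.normal(0, 0.05, len(t))
        (c,) = wa.extract_cycle_slopes(_measure_trace(t, y), settle_s=0.0)
        th = t / 3600.0
        beta = np.sum((th - th.mean()) * (y - y.mean())) / np.sum((th - th.mean()) ** 2)
        assert c.slope == pytest.approx(beta, rel=1e-9)
        assert abs(c.slope - (-120.0)) / 120.0 < 0.02

    def test_settle_window_discarded(self):
        t = np.arange(0.0, 300.0, 5.0)
        y = 100.0 - (2.0 / 60.0) * t
        y[t < 30] = 100.0  # mixing artifact before the settle cutoff
        (c,) = wa.extract_cycle_slopes(_measure_trace(t, y), settle_s=30.0)
        assert c.slope == pytest.approx(-120.0, rel=1e-9)

    def test_no_measure_phase_is_an_error(self):
        tr = OxygenTrace([0, 1, 2], [100, 99, 98], 21.0, ["flush"] * 3)
        with pytest.raises(InsufficientDataError):
            wa.extract_cycle_slopes(tr)


class TestBackgroundCorrection:
    def _cycle(self, t_mid, slope=-10.0):
        return wa.CycleMeasurement(t_mid - 50, t_mid + 50, slope, 1.0, 20)

    def test_zero_background_is_identity(self):
        (c,) = wa.background_correct([self._cycle(500.0)], 0.0, 0.0, 0.0, 1000.0)
        assert c.slope == -10.0

    def test_midpoint_interpolation(self):
        (c,) = wa.background_correct([self._cycle(500.0)], -1.0, -3.0, 0.0, 1000.0)
        assert c.slope == pytest.approx(-10.0 - (-2.0))
        assert c.background_subtracted == pytest.approx(-2.0)

    def test_endpoint_uses_pre_rate(self):
        (c,) = wa.background_correct([self._cycle(0.0)], -1.0, -3.0, 0.0, 1000.0)
        assert c.background_subtracted == pytest.approx(-1.0)

    def test_background_exceeding_fish_slope_flags_cycle(self):
        (c,) = wa.background_correct([self._cycle(500.0, -1.0)], -5.0, -5.0, 0.0, 1000.0)
        assert not c.quality_ok


class TestComputeMO2:
    def test_hand_computed_value(self):
        setup = RespirometrySetup(vr_l=4.0, mb_kg=0.114, temperature=21.0)
        c = wa.CycleMeasurement(0, 300, -3.0, 1.0, 60)
        expected = (4.0 - 0.114) * 3.0 * setup.alpha / 0.114
        assert wa.compute_mo2(c, setup) == pytest.approx(expected, rel=1e-12)
        assert wa.compute_mo2(c, setup) == pytest.approx(7.41, rel=0.02)

    def test_zero_slope_gives_zero(self):
        setup = RespirometrySetup(vr_l=4.0, mb_kg=0.114, temperature=21.0)
        assert wa.compute_mo2(wa.CycleMeasurement(0, 300, 0.0, 1.0, 60), setup) == 0.0

    @given(
        slope=st.floats(-200.0, -0.1),
        scale=st.floats(0.5, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_in_slope_inverse_in_mass(self, slope, scale):
        setup = RespirometrySetup(vr_l=8.0, mb_kg=0.114, temperature=21.0, vf_l=0.114)
        c1 = wa.CycleMeasurement(0, 300, slope, 1.0, 60)
        c2 = wa.CycleMeasurement(0, 300, slope * scale, 1.0, 60)
        assert wa.compute_mo2(c2, setup) == pytest.approx(
            scale * wa.compute_mo2(c1, setup), rel=1e-9
        )
        heavy = RespirometrySetup(
            vr_l=8.0, mb_kg=0.114 * scale, temperature=21.0, vf_l=0.114
        )
        assert wa.compute_mo2(c1, heavy) == pytest.approx(
            wa.compute_mo2(c1, setup) / scale, rel=1e-9
        )


def _series(values):
    return wa.MO2Series(
        [wa.MO2Entry(60.0 * i, v, True, True) for i, v in enumerate(values)]
    )


class TestSMR:
    def test_constant_series_recovered_exactly(self):
        smr, n = wa.estimate_smr(_series([132.3] * 15))
        assert smr == pytest.approx(132.3, rel=1e-12)
        assert n == 10

    def test_lowest_ten_forced_selection(self):
        smr, _ = wa.estimate_smr(_series([200.0] * 10 + [100.0] * 10))
        assert smr == pytest.approx(100.0)

    def test_empty_window_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            wa.estimate_smr(_series([100.0] * 12), window=(1e9, 2e9))

    def test_short_series_warns_and_uses_all(self):
        with pytest.warns(UserWarning):
            smr, n = wa.estimate_smr(_series([100.0] * 5))
        assert n == 5

    @pytest.mark.parametrize("seed", range(8))
    def test_generator_recovery_within_five_percent(self, seed):
        tr, truth = sy.gen_respirometry_trace(
            n_rest_cycles=60, n_chase_cycles=0, noise_sd=0.05, seed=seed
        )
        cyc = wa.background_correct(
            wa.extract_cycle_slopes(tr),
            truth.params["background_pre"],
            truth.params["background_post"],
            truth.params["t_pre"],
            truth.params["t_post"],
        )
        series = wa.mo2_series(cyc, sy.default_setup())
        smr, _ = wa.estimate_smr(series, window=(3600.0, tr.time[-1]))
        assert abs(smr / truth.params["smr"] - 1) < 0.05


class TestMMRScopeQ10:
    def test_max_of_series(self):
        mmr, _ = wa.estimate_mmr(_series([464.2, 300.0, 132.0]))
        assert mmr == 464.2

    def test_all_equal_series(self):
        mmr, _ = wa.estimate_mmr(_series([100.0] * 5))
        assert mmr == 100.0

    def test_noise_free_chase_recovers_mmr_exactly(self, small_respirometry):
        tr, truth = small_respirometry
        cyc = wa.background_correct(
            wa.extract_cycle_slopes(tr),
            truth.params["background_pre"],
            truth.params["background_post"],
            truth.params["t_pre"],
            truth.params["t_post"],
        )
        mmr, _ = wa.estimate_mmr(wa.mo2_series(cyc, sy.default_setup()))
        assert mmr == pytest.approx(truth.params["mmr"], rel=1e-9)

    def test_scope_identity_and_ordering_error(self):
        assert wa.aerobic_scope(132.3, 464.2) == pytest.approx(331.9)
        assert wa.aerobic_scope(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            wa.aerobic_scope(10.0, 5.0)

    def test_q10_definition_and_identities(self):
        assert wa.q10(100.0, 200.0, 15.0, 25.0) == pytest.approx(2.0)
        assert wa.q10(100.0, 100.0, 21.0, 25.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            wa.q10(-1.0, 100.0, 21.0, 25.0)
        with pytest.raises(ValueError):
            wa.q10(100.0, 120.0, 21.0, 21.0)

    @given(a=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_q10_scale_invariance(self, a):
        base = wa.q10(132.3, 178.3, 21.0, 25.0)
        assert wa.q10(a * 132.3, a * 178.3, 21.0, 25.0) == pytest.approx(base, rel=1e-9)


class TestOutliers:
    def test_single_extreme_value_flagged(self):
        mask = wa.flag_outliers([1.0, 1.0, 1.0, 1.0, 100.0])
        assert list(mask) == [False, False, False, False, True]

    def test_all_equal_flags_nothing(self):
        assert not wa.flag_outliers([5.0] * 6).any()

    def test_gaussian_tail_fraction_near_theory(self):
        rng = np.random.default_rng(123)
        frac = wa.flag_outliers(rng.standard_normal(1000)).mean()
        assert 0.03 < frac < 0.065  # two-sided tail mass beyond 2 SD ~ 4.6%
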