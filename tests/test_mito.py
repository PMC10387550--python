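"""Mitochondrial flux extraction, coupling ratios, P50 kinetics, Nernst dPsi."""

import numpy as np
import pytest

from aquaresp import mito as mt
from aquaresp import synthetic as sy
from aquaresp.traces import (
    ConfigurationError,
    InsufficientDataError,
    MitoTrace,
    ProtocolOrderError,
    TitrationEvent,
)


def _nernst(temp_c=21.0, chamber_ml=2.0, tissue_mg=5.0, fraction=0.198):
    return mt.NernstParams(
        temperature_k=temp_c + 273.15,
        chamber_volume_ml=chamber_ml,
        tissue_mass_mg=tissue_mg,
        mito_fraction=fraction,
    )


class TestJO2:
    def test_constant_concentration_gives_zero_flux(self):
        t = np.arange(0.0, 300.0)
        tr = MitoTrace(t, np.full(len(t), 150.0))
        j = mt.jo2_from_trace(tr, (50.0, 250.0), 5.0, 2.0)
        assert j == pytest.approx(0.0, abs=1e-9)

    def test_linear_decline_unit_conversion(self):
        # 0.1 uM/s over 2 mL and 5 mg -> 40 pmol s-1 mg-1
        t = np.arange(0.0, 300.0)
        tr = MitoTrace(t, 150.0 - 0.1 * t)
        j = mt.jo2_from_trace(tr, (50.0, 250.0), 5.0, 2.0)
        assert j == pytest.approx(40.0, rel=1e-9)

    def test_reoxygenation_step_yields_negative_flux(self):
        t = np.arange(0.0, 200.0)
        c = np.where(t < 100, 50.0 - 0.1 * t, 300.0)
        j = mt.jo2_series(MitoTrace(t, c), 5.0, 2.0)
        assert j.min() < 0  # titration artifact, caller flags

    def test_window_shorter_than_kernel_rejected(self):
        t = np.arange(0.0, 300.0)
        with pytest.raises(InsufficientDataError):
            mt.jo2_from_trace(MitoTrace(t, 150.0 - 0.1 * t), (0.0, 5.0), 5.0, 2.0)


class TestStates:
    def test_round_trip_recovers_piecewise_fluxes_exactly(self):
        tr, truth = sy.gen_mito_trace(seed=1)
        raw = mt.extract_states(tr, 5.0, 2.0)
        for state, want in truth.params["raw_fluxes"].items():
            assert raw.jo2(state) == pytest.approx(want, rel=1e-9)
        assert raw.jo2("ROX") == pytest.approx(truth.params["rox_flux"], rel=1e-9)
        assert raw.jo2("AZ_background") == pytest.approx(truth.params["az_flux"], rel=1e-9)

    def test_missing_uncoupler_leaves_other_states_intact(self):
        tr, truth = sy.gen_mito_trace(seed=1)
        events = [e for e in tr.events if e.reagent != "CCCP"]
        tr2 = MitoTrace(tr.time, tr.o2_conc, events, tr.fluorescence, tr.temperature)
        table = mt.extract_states(tr2, 5.0, 2.0)
        assert "ETS_uncoupled" not in table
        assert table.jo2("OXPHOS_CI") == pytest.approx(
            truth.params["raw_fluxes"]["OXPHOS_CI"], rel=1e-6
        )

    def test_out_of_order_events_rejected(self):
        t = np.arange(0.0, 600.0)
        events = [
            TitrationEvent(10.0, "succinate", 10.0),
            TitrationEvent(100.0, "ADP", 2.5),
        ]
        with pytest.raises(ProtocolOrderError):
            mt.extract_states(MitoTrace(t, 200.0 - 0.01 * t, events), 5.0, 2.0)

    def test_noisy_states_recovered_within_tolerance(self):
        tr, truth = sy.gen_mito_trace(noise_sd=0.1, noise_sd_fluor=0.005, seed=3)
        raw = mt.extract_states(tr, 5.0, 2.0)
        for state, want in truth.params["raw_fluxes"].items():
            tol = max(0.02 * want, 0.5)  # 2% or the flux resolution floor
            assert abs(raw.jo2(state) - want) < tol
        for state, want in truth.params["dpsi_per_state"].items():
            assert raw.dpsi(state) == pytest.approx(want, abs=1.5)


class TestRoxCorrection:
    def _table(self, **jo2s):
        t = mt.MitoStateTable()
        for k, v in jo2s.items():
            t.states[k] = mt.StateMeasure(v)
        return t

    def test_state_minus_rox(self):
        net = mt.rox_correct(self._table(OXPHOS_CI=50.0, ROX=5.0))
        assert net.jo2("OXPHOS_CI") == 45.0

    def test_zero_rox_is_identity(self):
        net = mt.rox_correct(self._table(OXPHOS_CI=50.0, ROX=0.0))
        assert net.jo2("OXPHOS_CI") == 50.0

    def test_cco_blanked_by_azide_not_rox(self):
        net = mt.rox_correct(
            self._table(CCO_raw=150.0, AZ_background=30.0, ROX=5.0)
        )
        assert net.cco_net == pytest.approx(120.0)
        assert net.jo2("CCO_raw") == 150.0  # untouched by ROX

    def test_missing_rox_leaves_fluxes_with_note(self):
        net = mt.rox_correct(self._table(OXPHOS_CI=50.0))
        assert not net.net
        assert any("uncorrected" in n for n in net.notes)

    def test_negative_net_flux_flagged_not_dropped(self):
        net = mt.rox_correct(self._table(Leak_CI=3.0, ROX=5.0))
        assert net.jo2("Leak_CI") == pytest.approx(-2.0)
        assert net.states["Leak_CI"].flagged


class TestRCR:
    def _net(self, ox, leak):
        t = mt.MitoStateTable(net=True)
        t.states["OXPHOS_CI_CII"] = mt.StateMeasure(ox)
        t.states["Leak_CI_CII"] = mt.StateMeasure(leak)
        return t

    def test_simple_ratio(self):
        assert mt.rcr(self._net(60.0, 5.0)) == pytest.approx(12.0)

    def test_fully_uncoupled_limit(self):
        assert mt.rcr(self._net(7.0, 7.0)) == pytest.approx(1.0)

    def test_non_positive_leak_undefined(self):
        with pytest.raises(ValueError):
            mt.rcr(self._net(60.0, 0.0))

    def test_out_of_band_value_logged_as_advisory(self):
        t = self._net(7.0, 7.0)
        mt.rcr(t)
        assert any("advisory" in n for n in t.notes)

    def test_generated_coupled_trace_recovers_rcr(self):
        tr, truth = sy.gen_mito_trace(noise_sd=0.05, seed=5)
        net = mt.rox_correct(mt.extract_states(tr, 5.0, 2.0))
        assert mt.rcr(net) == pytest.approx(truth.params["rcr"], rel=0.03)


class TestP50:
    def test_exact_model_data_recovered_to_numerical_precision(self):
        po2 = np.linspace(0.05, 20.0, 120)
        j = mt.hill(po2, 66.3, 2.0, 1.5)
        fit = mt.fit_p50(po2, j)
        assert fit.jmax == pytest.approx(66.3, rel=1e-6)
        assert fit.p50 == pytest.approx(2.0, rel=1e-6)
        assert fit.hill_h == pytest.approx(1.5, rel=1e-6)
        assert fit.accepted

    def test_noisy_median_error_below_ten_percent(self):
        errs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            po2 = np.linspace(0.05, 20.0, 200)
            j = mt.hill(po2, 66.3, 2.0, 1.5) + rng.normal(0.0, 0.05 * 66.3, 200)
            errs.append(abs(mt.fit_p50(po2, j).p50 - 2.0) / 2.0)
        assert np.median(errs) < 0.10

    def test_white_noise_fails_the_r2_gate(self):
        rng = np.random.default_rng(7)
        fit = mt.fit_p50(np.linspace(0.05, 20.0, 100), rng.normal(30.0, 10.0, 100))
        assert fit.r2 <= 0.70
        assert not fit.accepted

    def test_all_anoxic_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            mt.fit_p50(np.zeros(20), np.zeros(20))

    def test_trace_drawdown_segment_round_trip(self):
        tr, truth = sy.gen_mito_trace(seed=2)
        po2, jo2 = mt.p50_segment(tr, 5.0, 2.0)
        fit = mt.fit_p50(po2, jo2)
        assert fit.p50 == pytest.approx(truth.params["p50"], rel=1e-6)
        assert fit.hill_h == pytest.approx(truth.params["hill_h"], rel=1e-6)
        assert fit.jmax == pytest.approx(truth.params["jmax_raw"], rel=1e-6)


class TestNernst:
    def test_mass_balance_hand_value(self):
        p = _nernst(fraction=0.20)
        assert mt.safr_in_from_mass_balance(2.0, 1.8, p) == pytest.approx(401.8)

    def test_no_uptake_means_equal_concentrations(self):
        p = _nernst()
        assert mt.safr_in_from_mass_balance(2.0, 2.0, p) == pytest.approx(2.0)

    def test_halving_fraction_doubles_uptake_term(self):
        full = mt.safr_in_from_mass_balance(2.0, 1.8, _nernst(fraction=0.2))
        half = mt.safr_in_from_mass_balance(2.0, 1.8, _nernst(fraction=0.1))
        assert (half - 1.8) == pytest.approx(2 * (full - 1.8), rel=1e-9)

    def test_matrix_volume_must_stay_below_chamber(self):
        p = _nernst(chamber_ml=0.001, tissue_mg=10.0)
        with pytest.raises(ConfigurationError):
            mt.safr_in_from_mass_balance(2.0, 1.8, p)

    def test_mass_balance_closes(self):
        p = _nernst()
        out = 1.7
        inside = mt.safr_in_from_mass_balance(2.0, out, p)
        total = (out * p.v_chamber_ul + (inside - out) * p.v_mito_ul) / p.v_chamber_ul
        assert total == pytest.approx(2.0, rel=1e-9)

    def test_equal_concentrations_give_zero_potential(self):
        assert mt.membrane_potential(1.5, 1.5, _nernst()) == 0.0

    def test_decade_slope_at_21c(self):
        mv = mt.membrane_potential(1.0, 10.0, _nernst(temp_c=21.0))
        assert mv == pytest.approx(-58.36, abs=0.05)

    def test_antisymmetric_under_ratio_inversion(self):
        p = _nernst()
        assert mt.membrane_potential(3.0, 1.0, p) == pytest.approx(
            -mt.membrane_potential(1.0, 3.0, p), rel=1e-12
        )

    def test_control_anchor_ratio_337_gives_minus_147_5(self):
        p = _nernst(temp_c=21.0)
        ratio = 10.0 ** (147.5 / mt.nernst_slope_mv(294.15))
        assert mt.membrane_potential(1.0, ratio, p) == pytest.approx(-147.5, abs=1e-9)

    def test_trace_round_trip_recovers_dpsi_exactly(self):
        tr, truth = sy.gen_mito_trace(seed=4)
        raw = mt.extract_states(tr, 5.0, 2.0)
        for state, want in truth.params["dpsi_per_state"].items():
            assert raw.dpsi(state) == pytest.approx(want, rel=1e-9)


class TestWork:
    def test_hand_value_for_control_ci_oxphos(self):
        assert mt.mito_work(53.3, -147.5) == pytest.approx(0.361, abs=5e-4)

    def test_zero_flux_zero_work(self):
        assert mt.mito_work(0.0, -150.0) == 0.0

    def test_linear_in_flux(self):
        assert mt.mito_work(100.0, -150.0) == pytest.approx(
            2 * mt.mito_work(50.0, -150.0)
        )

    def test_zero_potential_undefined(self):
        with pytest.raises(ValueError):
            mt.mito_work(50.0, 0.0)
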