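"""Inverse computations: equilibrium, percent transport, Papp fits, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phoswell import (
    Condition,
    ConcentrationSeries,
    Layout,
    PhosphateTransportModel,
    SamplingPlan,
    TranswellGeometry,
    closed_form_concentrations,
    decompose_pathways,
    expected_equilibrium,
    headline_ratio,
    inhibitor_effect_ratio,
    mass_recovery,
    papp_from_percent_equilibrium,
    papp_nonsink_fit,
    papp_sink_slope,
    percent_transport,
    ter_normalize,
)
from phoswell.estimators import QCWarning, UndefinedTransportError, summarize_transport
from phoswell.kinetics import PermeabilityModel, overall_papp
from phoswell.synthetic import PRESET_MESO_LAYER

GEOM = TranswellGeometry()


class TestExpectedEquilibrium:
    @pytest.mark.parametrize(
        "c_a0, c_b0, expected",
        [(2.0, 1.2, 4 / 3), (1.0, 0.1, 0.25), (0.7, 0.7, 0.7)],
    )
    def test_volume_weighted_mean(self, c_a0, c_b0, expected):
        assert expected_equilibrium(c_a0, c_b0, GEOM) == pytest.approx(expected)


class TestPercentTransport:
    def _series(self, c_b_t):
        cond = Condition(layout=Layout.BLANK, apical_phosphate_mm=1.0, basolateral_phosphate_mm=0.1)
        # apical values by mass balance so both sides stay consistent
        c_a_t = 1.0 - (c_b_t - 0.1) * 5.0
        return ConcentrationSeries(cond, "w", [0.0, 3600.0], [1.0, c_a_t], [0.1, c_b_t])

    def test_no_transport_is_zero_percent(self):
        assert percent_transport(self._series(0.1))[-1] == 0.0

    def test_equilibrium_is_hundred_percent(self):
        assert percent_transport(self._series(0.25))[-1] == pytest.approx(100.0)

    def test_intermediate_value(self):
        assert percent_transport(self._series(0.18))[-1] == pytest.approx(53.3, abs=0.05)

    def test_no_gradient_raises(self):
        cond = Condition(layout=Layout.BLANK, apical_phosphate_mm=0.5, basolateral_phosphate_mm=0.5)
        s = ConcentrationSeries(cond, "w", [0.0, 3600.0], [0.5, 0.5], [0.5, 0.5])
        with pytest.raises(UndefinedTransportError):
            percent_transport(s)

    def test_apical_equals_basolateral_on_noiseless_series(self, make_noiseless_series):
        s = make_noiseless_series(7.74e-6)
        np.testing.assert_allclose(
            percent_transport(s, "apical"), percent_transport(s, "basolateral"), rtol=1e-10
        )


class TestSinkSlope:
    def _linear_series(self, c_a0=1.0, rise=0.01, t_end=4 * 3600.0):
        cond = Condition(layout=Layout.BLANK, apical_phosphate_mm=c_a0, basolateral_phosphate_mm=0.0)
        t = np.array([0.0, t_end / 2, t_end])
        c_b = rise * t / t_end
        c_a = np.full_like(t, c_a0)
        return ConcentrationSeries(cond, "w", t, c_a, c_b)

    def test_linear_rise_hand_value(self):
        # dQ/dt = 0.01 mM * 1000 µL / 14400 s; Papp = (dQ/dt)/(A * C0)
        papp = papp_sink_slope(self._linear_series(), GEOM, interval_s=(0, 4 * 3600.0))
        assert papp == pytest.approx(0.01 / 14400 / 0.33, rel=1e-9)  # 2.104e-6 cm/s

    def test_flat_receiver_gives_zero(self):
        papp = papp_sink_slope(self._linear_series(rise=0.0), GEOM, interval_s=(0, 4 * 3600.0))
        assert papp == 0.0

    def test_doubling_donor_halves_papp(self):
        p1 = papp_sink_slope(self._linear_series(c_a0=1.0), GEOM, (0, 4 * 3600.0))
        p2 = papp_sink_slope(self._linear_series(c_a0=2.0), GEOM, (0, 4 * 3600.0))
        assert p2 == pytest.approx(p1 / 2)

    def test_sink_violation_warns(self, make_noiseless_series):
        s = make_noiseless_series(7.74e-6)  # receiver starts at 10% of donor
        with pytest.warns(QCWarning, match="sink"):
            papp_sink_slope(s, GEOM)

    def test_underestimates_nonsink_far_from_sink(self, make_noiseless_series):
        s = make_noiseless_series(7.74e-6)
        with pytest.warns(QCWarning):
            sink = papp_sink_slope(s, GEOM, (0, 12 * 3600.0))
        assert sink < papp_nonsink_fit(s, GEOM)

    def test_discrepancy_shrinks_toward_sink_conditions(self, geom, make_noiseless_series):
        papp = 7.74e-6
        cond = Condition(layout=Layout.BLANK, apical_phosphate_mm=1.0, basolateral_phosphate_mm=0.0)
        short_t = np.array([0.0, 900.0, 1800.0, 2700.0])
        c_a, c_b = closed_form_concentrations(papp, geom, 1.0, 0.0, short_t)
        near_sink = ConcentrationSeries(cond, "w", short_t, c_a, c_b)
        far = make_noiseless_series(papp)  # starts at 0.1 mM receiver, runs 12 h
        err_near = abs(papp_sink_slope(near_sink, geom, (0.0, 2700.0)) / papp - 1)
        with pytest.warns(QCWarning):
            err_far = abs(papp_sink_slope(far, geom, (0.0, 12 * 3600.0)) / papp - 1)
        assert err_near < err_far
        assert err_near < 0.03


class TestNonSinkFit:
    @pytest.mark.parametrize("papp", [7.74e-6, 1.8e-5])
    def test_round_trip_identity(self, make_noiseless_series, papp):
        s = make_noiseless_series(papp)
        assert papp_nonsink_fit(s, GEOM) == pytest.approx(papp, rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        papp=st.floats(5e-7, 4e-5),
        c_a0=st.floats(0.5, 3.0),
        c_b0=st.floats(0.0, 0.4),
    )
    def test_inverse_of_simulator_across_draws(self, papp, c_a0, c_b0):
        times = np.array([0.0, 4 * 3600.0, 8 * 3600.0, 12 * 3600.0])
        c_a, c_b = closed_form_concentrations(papp, GEOM, c_a0, c_b0, times)
        cond = Condition(layout=Layout.BLANK, apical_phosphate_mm=c_a0, basolateral_phosphate_mm=c_b0)
        s = ConcentrationSeries(cond, "w", times, c_a, c_b)
        assert papp_nonsink_fit(s, GEOM) == pytest.approx(papp, rel=1e-7)

    def test_results_object_api(self, make_noiseless_series):
        res = PhosphateTransportModel(make_noiseless_series(7.74e-6), GEOM).fit()
        assert res.papp == pytest.approx(7.74e-6, rel=1e-9)
        assert res.nobs == 8
        assert "Papp" in res.summary()
        pred = res.predict([0.0, 3600.0])
        assert list(pred.columns) == ["time_s", "apical_mM", "basolateral_mM"]
        assert pred["apical_mM"].iloc[0] == pytest.approx(1.0)
        lo, hi = res.conf_int()
        assert lo <= res.papp <= hi

    def test_from_dataframe_selects_well(self, make_noiseless_series):
        s = make_noiseless_series(1e-5)
        df = s.to_frame()
        model = PhosphateTransportModel.from_dataframe(df, condition_id=s.condition.condition_id, replicate="w1")
        assert model.fit().papp == pytest.approx(1e-5, rel=1e-9)

    def test_too_few_points_rejected(self):
        cond = Condition(layout=Layout.BLANK)
        s = ConcentrationSeries(cond, "w", [0.0, 3600.0], [1.0, 0.9], [0.1, 0.15])
        with pytest.raises(ValueError, match="3 time points"):
            PhosphateTransportModel(s, GEOM).fit()


class TestInhibitorRatio:
    @pytest.mark.parametrize(
        "treated, control, pct, headline",
        [
            (5.56e-6, 7.45e-6, 74.6, 75.0),  # mesothelial monolayer, 2 mM
            (4.18e-6, 6.54e-6, 63.9, 65.0),  # co-culture, 1 mM
        ],
    )
    def test_printed_means_give_headline_figures(self, treated, control, pct, headline):
        r = inhibitor_effect_ratio(treated, control)
        assert r == pytest.approx(pct, abs=0.05)
        assert headline_ratio(r) == headline

    def test_no_effect_is_hundred(self):
        assert inhibitor_effect_ratio(3.3e-6, 3.3e-6) == 100.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            inhibitor_effect_ratio(1e-6, 0.0)


class TestTerNormalize:
    def test_blank_self_correction(self):
        assert ter_normalize(120.0, 120.0, 0.33) == 0.0

    def test_hand_value(self):
        assert ter_normalize(150.0, 120.0, 0.33) == pytest.approx(9.9)

    def test_unit_area_is_subtraction(self):
        assert ter_normalize(150.0, 120.0, 1.0) == 30.0

    def test_negative_flagged_not_clamped(self):
        with pytest.warns(QCWarning, match="below blank"):
            v = ter_normalize(100.0, 120.0, 0.33)
        assert v == pytest.approx(-6.6)


class TestMassRecovery:
    def test_closed_system_is_unity(self, make_noiseless_series):
        rec = mass_recovery(make_noiseless_series(1e-5), GEOM)
        np.testing.assert_allclose(rec, 1.0, rtol=1e-12)

    def test_basolateral_spill_fails_qc(self, make_noiseless_series):
        s = make_noiseless_series(1e-5)
        s.basolateral_mm = s.basolateral_mm.copy()
        s.basolateral_mm[-1] *= 0.8  # 20% of the receiver content lost
        rec = mass_recovery(s, GEOM)
        assert rec[-1] < 0.95
        summary = summarize_transport(s, GEOM)
        assert "recovery_out_of_band" in summary.qc_flags

    def test_withdrawal_bookkeeping_is_exact(self):
        from phoswell.synthetic import StudyArm, StudyDesign, generate_timeseries

        plan = SamplingPlan(withdrawal_volume_ul=10.0, mode="replace_blank")
        arm = StudyArm(Condition(layout=Layout.MESO_BASOLATERAL), (PRESET_MESO_LAYER,))
        design = StudyDesign(arms=[arm], replicates=1, noise_sd=0.0, noise_floor_mm=0.0,
                             sampling=plan, seed=1)
        study = generate_timeseries(design)
        rec = mass_recovery(study.series[0], GEOM, plan)
        np.testing.assert_allclose(rec, 1.0, rtol=1e-12)


class TestDecomposition:
    def test_recovers_pathways_from_noiseless_arms(self):
        m = PRESET_MESO_LAYER
        control = overall_papp(m)
        pfa = overall_papp(m, {"PFA"})
        both = overall_papp(m, {"PFA", "Tenapanor"})
        d = decompose_pathways(control, pfa, both, p_filter=m.p_filter,
                               efficacy_pfa=m.efficacy_pfa, efficacy_tena=m.efficacy_tena)
        assert d.p_trans == pytest.approx(m.p_trans, rel=1e-9)
        assert d.p_para == pytest.approx(m.p_para, rel=1e-9)
        # both pathways are fully accounted for, so nothing is unexplained
        assert d.p_insensitive == pytest.approx(0.0, abs=1e-12)
        assert d.scale == "cell-layer"
        assert not d.qc_flags

    def test_overall_scale_without_filter(self):
        d = decompose_pathways(7.18e-6, 5.29e-6, 5.43e-6)
        assert d.scale == "overall"
        assert d.ratio_pfa_pct == pytest.approx(73.7, abs=0.05)
        assert "negative_paracellular_estimate" in d.qc_flags  # 5.43 > 5.29

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            decompose_pathways(0.0, 1e-6, 1e-6)
        with pytest.raises(ValueError, match="filter"):
            decompose_pathways(2e-5, 1e-6, 1e-6, p_filter=1.8e-5)


def test_papp_from_percent_equilibrium_inverts_closed_form():
    pct = 78.1
    papp = papp_from_percent_equilibrium(pct, 12 * 3600.0, GEOM)
    c_eq = expected_equilibrium(1.0, 0.0, GEOM)
    _, c_b = closed_form_concentrations(papp, GEOM, 1.0, 0.0, 12 * 3600.0)
    assert c_b / c_eq * 100 == pytest.approx(pct, rel=1e-9)
    assert papp == pytest.approx(1.78e-5, rel=0.01)
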