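"""Renal and hepatic organ clearance models."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kirchpk import (
    HepaticParameters,
    InfeasibleModelError,
    InfeasibleObservationError,
    NonRateDefiningError,
    PerfusionSteadyState,
    RenalParameters,
    classify_rate_limiting_step,
    compare_ecc_vs_kirchhoff,
    ecc_clearance,
    entering_leaving_total,
    hepatic_bioavailability,
    hepatic_clearance,
    hepatic_transport_limited,
    intrinsic_clearance_from_perfusion,
    metformin_renal,
    renal_clearance,
    renal_net_secretion_from_observed,
    well_stirred_form,
)
from kirchpk.units import l_h_to_ml_min

flows = st.floats(min_value=1.0, max_value=200.0)
fub = st.floats(min_value=0.01, max_value=1.0)
clint = st.floats(min_value=0.1, max_value=1e4)


class TestRenal:
    def test_metformin_observed_clearance(self):
        # Q_R 1200, f_uB 1, GFR 120, net secretion 1080 (all mL/min) -> 600
        assert l_h_to_ml_min(renal_clearance(metformin_renal())) == pytest.approx(
            600.0, rel=1e-9
        )

    def test_filtration_only_limit(self):
        p = RenalParameters(Q_R=1e9, f_uB=0.5, GFR=7.2)
        assert renal_clearance(p) == pytest.approx(0.5 * 7.2, rel=1e-6)

    def test_net_reabsorption_exceeding_filtration_raises(self):
        p = RenalParameters(Q_R=72.0, f_uB=1.0, GFR=7.2, CL_sec=1.0, CL_reab=10.0)
        with pytest.raises(NonRateDefiningError):
            renal_clearance(p)

    @given(flows, fub, st.floats(min_value=0.5, max_value=10.0),
           st.floats(min_value=0.0, max_value=60.0))
    def test_matches_entering_leaving_composition(self, qr, f, gfr, sec):
        p = RenalParameters(Q_R=qr, f_uB=f, GFR=gfr, CL_sec=sec)
        expected = (
            entering_leaving_total([qr], [f * gfr, sec])
            if sec > 0
            else entering_leaving_total([qr], [f * gfr])
        )
        assert renal_clearance(p) == pytest.approx(expected, rel=1e-12)

    @given(flows, fub, st.floats(min_value=0.5, max_value=10.0),
           st.floats(min_value=0.01, max_value=60.0))
    def test_clearance_always_below_blood_flow(self, qr, f, gfr, sec):
        p = RenalParameters(Q_R=qr, f_uB=f, GFR=gfr, CL_sec=sec)
        assert renal_clearance(p) < qr


class TestRenalInversion:
    def test_metformin_net_secretion_with_blood_flow(self):
        net = renal_net_secretion_from_observed(600, 1200, 1.0, 120, True)
        assert net == pytest.approx(1080.0, rel=1e-9)

    def test_metformin_traditional_flow_free_estimate(self):
        net = renal_net_secretion_from_observed(600, 1200, 1.0, 120, False)
        assert net == pytest.approx(480.0, rel=1e-9)

    def test_pure_filtration_gives_zero_net(self):
        net = renal_net_secretion_from_observed(120.0, 1e12, 1.0, 120.0, True)
        assert net == pytest.approx(0.0, abs=1e-6)

    def test_observed_clearance_at_blood_flow_is_infeasible(self):
        with pytest.raises(InfeasibleObservationError):
            renal_net_secretion_from_observed(1200, 1200, 1.0, 120, True)

    @given(flows, fub, st.floats(min_value=0.5, max_value=10.0),
           st.floats(min_value=0.01, max_value=60.0),
           st.floats(min_value=0.0, max_value=0.009))
    def test_round_trip_recovers_net_transport(self, qr, f, gfr, sec, reab):
        p = RenalParameters(Q_R=qr, f_uB=f, GFR=gfr, CL_sec=sec, CL_reab=reab)
        clr = renal_clearance(p)
        net = renal_net_secretion_from_observed(clr, qr, f, gfr, True)
        assert net == pytest.approx(p.net_transport, rel=1e-9, abs=1e-9)


class TestHepatic:
    def test_blood_flow_limit_at_high_intrinsic_clearance(self):
        p = HepaticParameters(Q_H=90.0, f_uB=1.0, CL_int=1e12)
        assert hepatic_clearance(p) == pytest.approx(90.0, rel=1e-9)

    def test_three_stage_series_hand_value(self):
        p = HepaticParameters(
            Q_H=90.0, f_uB=0.1, CL_int=500.0,
            CL_int_influx=60.0, CL_int_efflux=10.0, transport_in_scope=True,
        )
        # 1/(1/90 + 1/(0.1*50) + 1/(0.1*500))
        assert hepatic_clearance(p) == pytest.approx(
            1 / (1 / 90 + 1 / 5 + 1 / 50), rel=1e-12
        )

    def test_without_transport_equals_well_stirred_form(self):
        p = HepaticParameters(Q_H=90.0, f_uB=0.1, CL_int=500.0)
        assert hepatic_clearance(p) == pytest.approx(
            well_stirred_form(90.0, 0.1, 500.0), rel=1e-12
        )
        assert hepatic_clearance(p) == pytest.approx(90 * 50 / 140, rel=1e-12)

    def test_nonpositive_net_transport_raises(self):
        p = HepaticParameters(
            Q_H=90.0, f_uB=0.1, CL_int=500.0,
            CL_int_influx=5.0, CL_int_efflux=5.0, transport_in_scope=True,
        )
        with pytest.raises(NonRateDefiningError):
            hepatic_clearance(p)

    @given(flows, fub, clint)
    def test_clearance_always_below_blood_flow(self, qh, f, ci):
        p = HepaticParameters(Q_H=qh, f_uB=f, CL_int=ci)
        assert hepatic_clearance(p) < qh


class TestWellStirredForm:
    def test_high_extraction_limit_is_blood_flow(self):
        assert well_stirred_form(90.0, 1.0, 1e12) == pytest.approx(90.0, rel=1e-9)

    def test_restrictive_limit_is_fub_clint(self):
        assert well_stirred_form(1e9, 0.1, 500.0) == pytest.approx(50.0, rel=1e-6)

    def test_hand_value(self):
        assert well_stirred_form(90.0, 0.1, 500.0) == pytest.approx(
            90 * 50 / (90 + 50), rel=1e-12
        )


class TestTransportLimited:
    def test_fast_transport_boundary_is_elimination_limited(self):
        p = HepaticParameters(Q_H=90, f_uB=0.5, CL_int=40.0, CL_int_influx=1e9)
        assert hepatic_transport_limited(p) == pytest.approx(0.5 * 40.0, rel=1e-6)

    def test_slow_transport_boundary_is_net_flux(self):
        p = HepaticParameters(
            Q_H=90, f_uB=0.5, CL_int=1e9, CL_int_influx=30.0, CL_int_efflux=10.0
        )
        assert hepatic_transport_limited(p) == pytest.approx(0.5 * 20.0, rel=1e-6)

    def test_hand_value(self):
        p = HepaticParameters(
            Q_H=90, f_uB=0.5, CL_int=40.0, CL_int_influx=30.0, CL_int_efflux=10.0
        )
        assert hepatic_transport_limited(p) == pytest.approx(
            0.5 * 40 * 20 / 60, rel=1e-12
        )


class TestECC:
    def test_zero_efflux_reduces_to_fub_influx(self):
        p = HepaticParameters(
            Q_H=90, f_uB=0.3, CL_int=40.0, CL_int_influx=5.0, CL_int_efflux=0.0
        )
        assert ecc_clearance(p, simplified=True) == pytest.approx(
            0.3 * 5.0 * 40 / 40, rel=1e-12
        )

    def test_influx_equal_efflux_much_greater_than_clint_gives_fub_clint(self):
        p = HepaticParameters(
            Q_H=90, f_uB=0.3, CL_int=1.0, CL_int_influx=1e7, CL_int_efflux=1e7
        )
        assert ecc_clearance(p, simplified=True) == pytest.approx(0.3, rel=1e-6)

    def test_full_form_approaches_simplified_as_qh_grows(self):
        p = HepaticParameters(
            Q_H=1e12, f_uB=0.3, CL_int=40.0, CL_int_influx=5.0, CL_int_efflux=2.0
        )
        assert ecc_clearance(p, simplified=False) == pytest.approx(
            ecc_clearance(p, simplified=True), rel=1e-9
        )

    def test_convergence_in_qh_is_monotone(self):
        base = dict(f_uB=0.3, CL_int=40.0, CL_int_influx=5.0, CL_int_efflux=2.0)
        limit = ecc_clearance(HepaticParameters(Q_H=1.0, **base), simplified=True)
        ratios = [
            ecc_clearance(HepaticParameters(Q_H=q, **base), simplified=False) / limit
            for q in np.logspace(0, 6, 13)
        ]
        assert all(np.diff(ratios) > 0)
        assert ratios[-1] == pytest.approx(1.0, rel=1e-4)

    def test_negative_net_transport_is_permitted(self):
        # the ECC keeps influx and efflux separate, so influx < efflux is valid
        p = HepaticParameters(
            Q_H=90, f_uB=0.3, CL_int=40.0, CL_int_influx=2.0, CL_int_efflux=5.0
        )
        assert ecc_clearance(p, simplified=True) > 0


class TestCompareFrameworks:
    def test_passive_transport_case_only_ecc_yields_a_value(self):
        p = HepaticParameters(
            Q_H=90, f_uB=0.3, CL_int=40.0, CL_int_influx=5.0, CL_int_efflux=5.0
        )
        r = compare_ecc_vs_kirchhoff(p)
        assert r["CL_ecc"] is not None
        assert r["CL_kirchhoff"] is None
        assert "rate-defining" in r["kirchhoff_note"]

    def test_zero_efflux_small_influx_both_approach_fub_influx(self):
        p = HepaticParameters(
            Q_H=90, f_uB=0.3, CL_int=4000.0, CL_int_influx=5.0, CL_int_efflux=0.0
        )
        r = compare_ecc_vs_kirchhoff(p)
        assert r["CL_ecc"] == pytest.approx(0.3 * 5.0, rel=1e-12)
        assert r["CL_kirchhoff"] == pytest.approx(0.3 * 5.0, rel=2e-3)
        # the frameworks differ by exactly CL_int/(CL_int + net)
        assert r["ratio_ecc_over_kirchhoff"] == pytest.approx(
            (4000.0 + 5.0) / 4000.0, rel=1e-9
        )

    @given(flows, fub, clint, st.floats(min_value=0.1, max_value=100.0),
           st.floats(min_value=0.0, max_value=100.0))
    def test_report_never_raises_over_parameter_sweep(self, qh, f, ci, inf, eff):
        p = HepaticParameters(
            Q_H=qh, f_uB=f, CL_int=ci, CL_int_influx=inf, CL_int_efflux=eff
        )
        r = compare_ecc_vs_kirchhoff(p)
        assert (r["CL_ecc"] is not None) or r["ecc_note"]
        if inf > eff:
            assert r["CL_kirchhoff"] is not None


class TestRateLimitClassification:
    def test_tiny_blood_flow_dominates(self):
        p = HepaticParameters(Q_H=0.01, f_uB=1.0, CL_int=1000.0)
        assert classify_rate_limiting_step(p).label == "blood_flow_limited"

    def test_small_net_transport_dominates(self):
        p = HepaticParameters(
            Q_H=1000.0, f_uB=1.0, CL_int=1000.0,
            CL_int_influx=11.0, CL_int_efflux=1.0, transport_in_scope=True,
        )
        assert classify_rate_limiting_step(p).label == "net_transport_limited"

    def test_balanced_stages_are_mixed(self):
        p = HepaticParameters(
            Q_H=10.0, f_uB=1.0, CL_int=10.0,
            CL_int_influx=11.0, CL_int_efflux=1.0, transport_in_scope=True,
        )
        c = classify_rate_limiting_step(p, dominance_fraction=0.9)
        assert c.label == "mixed"
        assert c.dominance_ratio == pytest.approx(1 / 3, rel=1e-9)


class TestPerfusion:
    def test_zero_extraction_limit_models_agree(self):
        ss = PerfusionSteadyState(
            C_in_u=10.0, C_out_u=9.999, C_blood=10.0, Q_H=1.0, f_uB=1.0
        )
        wsm = intrinsic_clearance_from_perfusion(ss, "WSM")
        ptm = intrinsic_clearance_from_perfusion(ss, "PTM")
        assert wsm == pytest.approx(ptm, rel=1e-3)

    def test_log_mean_identity(self):
        ss = PerfusionSteadyState(
            C_in_u=10.0, C_out_u=1.0, C_blood=10.0, Q_H=1.0, f_uB=1.0
        )
        cl_h = 1.0 * (10 - 1) / 10
        log_mean = (10 - 1) / np.log(10.0)
        assert intrinsic_clearance_from_perfusion(ss, "WSM") == pytest.approx(
            cl_h * 10 / 1.0, rel=1e-12
        )
        assert intrinsic_clearance_from_perfusion(ss, "PTM") == pytest.approx(
            cl_h * 10 / log_mean, rel=1e-12
        )

    @given(st.floats(min_value=0.05, max_value=0.95))
    def test_wsm_intrinsic_clearance_exceeds_ptm(self, extraction):
        ss = PerfusionSteadyState(
            C_in_u=10.0, C_out_u=10.0 * (1 - extraction), C_blood=10.0,
            Q_H=5.0, f_uB=0.5,
        )
        wsm = intrinsic_clearance_from_perfusion(ss, "WSM")
        ptm = intrinsic_clearance_from_perfusion(ss, "PTM")
        assert wsm > ptm


class TestHepaticBioavailability:
    @pytest.mark.parametrize(
        "cl,q,expected", [(45.0, 90.0, 0.5), (1e-9, 90.0, 1.0), (10.4, 90.0, 0.884)]
    )
    def test_values(self, cl, q, expected):
        assert hepatic_bioavailability(cl, q) == pytest.approx(expected, abs=5e-4)

    def test_clearance_at_or_above_flow_is_infeasible(self):
        with pytest.raises(InfeasibleModelError):
            hepatic_bioavailability(90.0, 90.0)
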