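"""Deterministic model: closed forms, balances, monotonicity, gates."""

import numpy as np
import pytest
from dataclasses import replace

from tunedev.kinetic_model import (
    CHARACTERIZATION,
    LOW_COPY,
    NOMINAL,
    DelayTimes,
    GateParameters,
    HostParameters,
    SteadyStateError,
    TESParameters,
    UndefinedRatioError,
    build_tes_network,
    coupled_steady_state,
    fold_change_profile,
    nor_gate_response,
    not_gate_response,
    response_surface,
    rnap_to_rpu,
    rpu_to_rnap,
    simulate_dde_timecourse,
    simulate_ode_timecourse,
    steady_state,
    tes_rhs,
    ths_tuner_ratio,
)

MODEL_TUNER_GRID = (0.0001, 0.06, 0.3, 1.5, 7.6, 38.0, 190.0)


def closed_form_no_binding_protein(p: TESParameters) -> float:
    return p.k_leak * p.u_in / ((p.delta_m + p.phi) * (p.delta_p + p.phi))


class TestSteadyState:
    def test_no_binding_limit_matches_closed_form(self):
        p = replace(NOMINAL, k_on=0.0)
        st = steady_state(p)
        assert st.p == pytest.approx(closed_form_no_binding_protein(p), rel=1e-9)
        assert st.c == 0.0
        assert st.m == pytest.approx(p.u_in / (p.delta_m + p.phi), rel=1e-12)

    @pytest.mark.parametrize("params", [NOMINAL, LOW_COPY, CHARACTERIZATION,
                                        replace(NOMINAL, k_off=0.5)])
    def test_steady_state_zeroes_the_rhs(self, params):
        st = steady_state(params)
        resid = np.abs(tes_rhs(params, st.as_array()))
        scale = max(params.u_in, params.booster_factor * params.u_tun, 1.0)
        assert np.all(resid <= 1e-9 * scale)

    def test_steady_state_matches_long_integration(self):
        p = LOW_COPY.with_inputs(u_in=3.0, u_tun=10.0)
        st = steady_state(p)
        frame = simulate_ode_timecourse(p, np.zeros(4), duration=3000.0, n_points=11)
        final = frame[["m", "s", "c", "p"]].iloc[-1].to_numpy()
        np.testing.assert_allclose(final, st.as_array(), rtol=1e-6, atol=1e-8)

    def test_unbounded_complex_accumulation_is_rejected(self):
        p = replace(NOMINAL, k_off=0.0, delta_c=0.0, phi=0.0, delta_p=0.1)
        with pytest.raises(SteadyStateError):
            steady_state(p)

    def test_zero_tuner_gives_pure_leak_output(self):
        p = NOMINAL.with_inputs(u_tun=0.0)
        st = steady_state(p)
        assert st.p == pytest.approx(closed_form_no_binding_protein(p), rel=1e-9)


class TestMassBalances:
    def test_binding_terms_cancel_in_rna_moiety_balances(self):
        # d(m+c)/dt and d(s+c)/dt contain no binding contribution: the
        # bilinear terms cancel exactly, leaving production minus decay.
        rng = np.random.default_rng(42)
        p = replace(NOMINAL, k_on=0.03, k_off=0.7)
        for _ in range(50):
            x = rng.uniform(0.0, 50.0, 4)
            d = tes_rhs(p, x)
            gm, gs, gc = (p.delta_m + p.phi), (p.delta_s + p.phi), (p.delta_c + p.phi)
            assert d[0] + d[2] == pytest.approx(p.u_in - gm * x[0] - gc * x[2], abs=1e-10)
            assert d[1] + d[2] == pytest.approx(
                p.booster_factor * p.u_tun - gs * x[1] - gc * x[2], abs=1e-10
            )

    def test_network_rhs_agrees_with_hand_written_rhs(self):
        rng = np.random.default_rng(7)
        net = build_tes_network(LOW_COPY)
        for _ in range(20):
            x = rng.uniform(0.0, 30.0, 4)
            np.testing.assert_allclose(net.ode_rhs(0.0, x), tes_rhs(LOW_COPY, x), rtol=1e-12)

    def test_propensities_use_falling_factorials(self):
        net = build_tes_network(replace(NOMINAL, k_on=1.0))
        # binding propensity at m=1, s=1 is k_on * 1 * 1; at m=0 it vanishes
        a = net.propensities(np.array([1, 1, 0, 0]))
        assert a[2] == pytest.approx(1.0)
        a = net.propensities(np.array([0, 5, 0, 0]))
        assert a[2] == 0.0


class TestTunerResponse:
    def test_output_strictly_increases_with_tuner_activity(self):
        surface = response_surface(NOMINAL, [1.0, 10.0, 100.0], MODEL_TUNER_GRID)
        for _, group in surface.groupby("input_activity"):
            out = group.sort_values("tuner_activity")["output"].to_numpy()
            assert np.all(np.diff(out) > 0)

    def test_fold_change_non_increasing_in_tuner(self):
        prof = fold_change_profile(NOMINAL, u_in_low=rpu_to_rnap(0.002),
                                   u_in_high=rpu_to_rnap(6.6),
                                   tuner_grid=MODEL_TUNER_GRID)
        fold = prof["fold_change"].to_numpy()
        assert np.all(np.diff(fold) <= fold[:-1] * 1e-12)

    def test_tuner_ratio_counts_complex_in_both_pools(self):
        p = LOW_COPY.with_inputs(u_in=2.0, u_tun=2.0)
        st = steady_state(p)
        assert ths_tuner_ratio(p) == pytest.approx((st.m + st.c) / (st.s + st.c))
        assert ths_tuner_ratio(p, include_complex=False) == pytest.approx(st.m / st.s)

    def test_tuner_ratio_undefined_without_srna(self):
        with pytest.raises(UndefinedRatioError):
            ths_tuner_ratio(NOMINAL.with_inputs(u_tun=0.0))

    def test_booster_raises_output_at_every_tuner_level(self):
        for u_tun in MODEL_TUNER_GRID:
            base = steady_state(NOMINAL.with_inputs(u_tun=u_tun)).p
            boosted = steady_state(
                replace(NOMINAL.with_inputs(u_tun=u_tun), booster_factor=5.0)
            ).p
            assert boosted >= base


class TestGates:
    def test_not_gate_output_decreases_with_input(self):
        gate = GateParameters()
        outs = [not_gate_response(CHARACTERIZATION, gate, u_in=u, u_tun=30.0)
                for u in (0.1, 1.0, 10.0, 100.0)]
        assert np.all(np.diff(outs) < 0)

    def test_nor_gate_is_symmetric_in_its_inputs(self):
        gate = GateParameters()
        a = nor_gate_response(CHARACTERIZATION, gate, u_a=2.0, u_b=40.0, u_tun=30.0)
        b = nor_gate_response(CHARACTERIZATION, gate, u_a=40.0, u_b=2.0, u_tun=30.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_nor_gate_truth_table_corners(self):
        gate = GateParameters()
        lo, hi = 0.1, 300.0
        out = {
            (a, b): nor_gate_response(CHARACTERIZATION, gate, u_a=a, u_b=b, u_tun=30.0)
            for a in (lo, hi) for b in (lo, hi)
        }
        # high output only when both inputs are low
        assert out[(lo, lo)] > 5 * max(out[(lo, hi)], out[(hi, lo)], out[(hi, hi)])

    def test_readthrough_raises_not_gate_repressor(self):
        insulated = GateParameters(kappa_rt=0.0)
        leaky = GateParameters(kappa_rt=5.0)
        u = 1.0
        assert (not_gate_response(CHARACTERIZATION, leaky, u_in=u, u_tun=30.0)
                < not_gate_response(CHARACTERIZATION, insulated, u_in=u, u_tun=30.0))


class TestResourceCoupling:
    def test_coupling_lowers_protein_output(self):
        host = HostParameters(R_total=16000.0, host_demand=15000.0)
        free = steady_state(NOMINAL)
        coupled = coupled_steady_state(NOMINAL, host)
        assert coupled.p < free.p
        np.testing.assert_allclose(
            [coupled.m, coupled.s, coupled.c], [free.m, free.s, free.c], rtol=1e-9
        )

    def test_coupling_vanishes_with_abundant_ribosomes(self):
        host = HostParameters(R_total=1e9, host_demand=100.0, K_rib=1.0)
        free = steady_state(NOMINAL)
        coupled = coupled_steady_state(NOMINAL, host)
        assert coupled.p == pytest.approx(free.p, rel=1e-6)


class TestDelayModel:
    def test_zero_delays_reduce_to_ode(self):
        p = LOW_COPY.with_inputs(u_in=2.0, u_tun=5.0)
        ode = simulate_ode_timecourse(p, np.zeros(4), duration=30.0, n_points=31)
        dde = simulate_dde_timecourse(p, DelayTimes(), np.zeros(4), duration=30.0, n_points=31)
        np.testing.assert_allclose(
            dde[["m", "s", "c", "p"]].to_numpy(),
            ode[["m", "s", "c", "p"]].to_numpy(), rtol=1e-4, atol=1e-6,
        )

    def test_translation_delay_postpones_protein_rise(self):
        p = NOMINAL
        delayed = simulate_dde_timecourse(
            p, DelayTimes(translation=10.0), np.zeros(4), duration=30.0, n_points=61
        )
        plain = simulate_dde_timecourse(
            p, DelayTimes(), np.zeros(4), duration=30.0, n_points=61
        )
        early = delayed["time"] < 10.0
        assert np.all(delayed.loc[early, "p"] <= 1e-9)
        assert plain.loc[early, "p"].iloc[-1] > 1.0


class TestValidationAndUnits:
    def test_invalid_parameter_errors_name_the_field(self):
        with pytest.raises(ValueError, match="delta_m"):
            TESParameters(delta_m=-1.0)
        with pytest.raises(ValueError, match="k_act"):
            TESParameters(k_act=0.001, k_leak=0.02)
        with pytest.raises(ValueError, match="booster_factor"):
            TESParameters(booster_factor=0.5)

    def test_rpu_bridge_round_trip(self):
        assert rnap_to_rpu(rpu_to_rnap(0.43)) == pytest.approx(0.43, rel=1e-12)
        assert rpu_to_rnap(1.0) == pytest.approx(79.0)

    def test_with_inputs_replaces_only_promoter_activities(self):
        p = NOMINAL.with_inputs(u_in=9.0)
        assert p.u_in == 9.0
        assert p.u_tun == NOMINAL.u_tun
        assert p.k_on == NOMINAL.k_on
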