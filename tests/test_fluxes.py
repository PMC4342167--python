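"""Unit behaviour of the individual rate laws, carriers and currents."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ngvsim as ngv
from ngvsim import fluxes as fx
from ngvsim.errors import ModelDomainError
from ngvsim.state import resting_state

P = ngv.ParameterSet()
conc = st.floats(min_value=0.0, max_value=50.0)


# ----------------------------------------------------------------------
# reversible carrier
# ----------------------------------------------------------------------
class TestCarrier:
    def test_equal_concentrations_give_zero(self):
        assert fx.carrier_flux(1.3, 1.3, 2.0, 5.0) == 0.0

    def test_saturation_limit(self):
        assert fx.carrier_flux(1e9, 0.0, 2.0, 5.0) == pytest.approx(2.0, rel=1e-8)

    def test_half_saturation(self):
        assert fx.carrier_flux(5.0, 0.0, 2.0, 5.0) == pytest.approx(1.0)

    @given(conc, conc)
    def test_antisymmetry(self, a, b):
        fwd = fx.carrier_flux(a, b, 0.7, 3.0)
        rev = fx.carrier_flux(b, a, 0.7, 3.0)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ModelDomainError):
            fx.carrier_flux(-0.1, 1.0, 1.0, 1.0)


# ----------------------------------------------------------------------
# glycolysis
# ----------------------------------------------------------------------
class TestGlycolysis:
    def _state(self, **over):
        y = {n: resting_state()[i] for n, i in ngv.STATE_INDEX.items()}
        y.update(over)
        return y

    def test_no_glucose_no_hkpfk(self):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.glycolysis_fluxes(self._state(GLC_n=0.0), aden, P, "neuron")
        assert out["J_HKPFK"] == 0.0

    @pytest.mark.parametrize("over", [{"GAP_n": 0.0}])
    def test_no_gap_no_pgk(self, over):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.glycolysis_fluxes(self._state(**over), aden, P, "neuron")
        assert out["J_PGK"] == 0.0

    def test_exhausted_nad_stops_pgk(self):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.glycolysis_fluxes(self._state(NADH_cyto_n=P.n_tot), aden, P, "neuron")
        assert out["J_PGK"] == 0.0

    def test_atp_inhibition_reduces_hkpfk(self):
        aden = fx.adenylate_closure(2.2, P)
        lo = fx.glycolysis_fluxes(self._state(ATP_n=1.0), fx.adenylate_closure(1.0, P), P, "neuron")
        hi = fx.glycolysis_fluxes(self._state(ATP_n=2.2), aden, P, "neuron")
        # per unit ATP the flux falls when the inhibition term engages
        assert hi["J_HKPFK"] / 2.2 < lo["J_HKPFK"] / 1.0


# ----------------------------------------------------------------------
# lactate dehydrogenase
# ----------------------------------------------------------------------
class TestLDH:
    def test_no_substrates_no_flux(self):
        assert fx.ldh_flux(0.0, 0.0, 0.0, P, "neuron") == 0.0

    def test_equilibrium_redox_ratio_balances(self):
        # choose NADH so that k+ PYR NADH = k- LAC (N-NADH) at PYR=LAC
        k, km = P.kp_ldh_n, P.km_ldh_n
        nadh = P.n_tot * km / (k + km)
        assert fx.ldh_flux(0.3, nadh, 0.3, P, "neuron") == pytest.approx(0.0, abs=1e-15)

    def test_neuron_rest_runs_lactate_to_pyruvate(self):
        # frozen from direct evaluation at the published resting values
        j = fx.ldh_flux(0.17, 0.006, 0.6, P, "neuron")
        assert j == pytest.approx(-0.015246, rel=1e-6)
        assert j < 0.0  # neurons consume lactate at rest

    def test_astrocyte_rest_produces_lactate(self):
        j = fx.ldh_flux(0.17, 0.1, 0.6, P, "astrocyte")
        assert j == pytest.approx(0.0222588, rel=1e-6)
        assert j > 0.0


# ----------------------------------------------------------------------
# mitochondria and shuttle
# ----------------------------------------------------------------------
class TestMito:
    def _state(self, **over):
        y = {n: resting_state()[i] for n, i in ngv.STATE_INDEX.items()}
        y.update(over)
        return y

    def test_no_oxygen_stops_etc(self):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.mito_fluxes(self._state(O2_n=0.0), aden, P, "neuron")
        assert out["J_mito_out"] == 0.0

    def test_exhausted_mito_nad_stops_tca(self):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.mito_fluxes(self._state(NADH_mito_n=P.n_tot), aden, P, "neuron")
        assert out["J_mito_in"] == 0.0

    def test_saturated_etc_reaches_vmax(self):
        # with vanishing affinities every saturation term -> 1
        p2 = P.replace(k_m_adp_n=1e-12, k_m_nadh_n=1e-12, k_o2_mito=1e-12)
        aden = fx.adenylate_closure(1.0, p2)  # plentiful ADP
        out = fx.mito_fluxes(
            self._state(O2_n=100.0, NADH_mito_n=0.21, ATP_n=1.0), aden, p2, "neuron"
        )
        assert out["J_mito_out"] == pytest.approx(P.vmax_out_n, rel=1e-6)

    def test_shuttle_vanishes_at_redox_extremes(self):
        assert fx.nadh_shuttle_flux(1e-14, 0.12, P, "neuron") == pytest.approx(0.0, abs=1e-6)
        assert fx.nadh_shuttle_flux(0.006, P.n_tot - 1e-14, P, "neuron") == pytest.approx(0.0, abs=1e-6)

    def test_shuttle_saturates_at_capacity(self):
        # R- >> M_cyto and R+ >> M_mito
        j = fx.nadh_shuttle_flux(P.n_tot - 1e-9, 1e-9, P, "astrocyte")
        assert j == pytest.approx(P.t_nadh_g, rel=1e-3)

    def test_shuttle_rejects_boundary_pools(self):
        with pytest.raises(ModelDomainError):
            fx.nadh_shuttle_flux(0.0, 0.12, P, "neuron")


class TestCreatineKinase:
    def test_full_pcr_without_adp_is_inert(self):
        assert fx.creatine_kinase_flux(0.0, 2.2, P.c_tot, P, "neuron") == 0.0

    def test_equilibrium(self):
        adp, atp = 0.0119, 2.2
        pcr = 4.9
        km = P.kp_ck_n * adp * pcr / (atp * (P.c_tot - pcr))
        p2 = P.replace(km_ck_n=km)
        assert fx.creatine_kinase_flux(adp, atp, pcr, p2, "neuron") == pytest.approx(0.0, abs=1e-15)

    def test_rest_value_small_forward(self):
        adp = fx.adenylate_closure(2.2, P).adp
        j = fx.creatine_kinase_flux(adp, 2.2, 4.9, P, "neuron")
        expected = P.kp_ck_n * adp * 4.9 - P.km_ck_n * 2.2 * 5.1  # direct arithmetic
        assert j == pytest.approx(expected, rel=1e-12)
        assert abs(j) < 1e-3


# ----------------------------------------------------------------------
# pump, leak, oxygen, capillary
# ----------------------------------------------------------------------
class TestPumpLeak:
    def test_neuron_rest_pump_flux(self):
        out = fx.pump_and_leak(8.0, 2.2, -73.0, P, "neuron")
        assert out["J_pump"] == pytest.approx(0.17926, rel=1e-4)

    def test_leak_vanishes_at_nernst_potential(self):
        na = 8.0
        psi = P.rt_f * np.log(P.na_e / na)
        out = fx.pump_and_leak(na, 2.2, psi, P, "neuron")
        assert out["J_leak_Na"] == pytest.approx(0.0, abs=1e-12)

    def test_no_atp_no_pump(self):
        out = fx.pump_and_leak(8.0, 0.0, -73.0, P, "neuron")
        assert out["J_pump"] == 0.0

    def test_astrocyte_rest_pump_matches_baseline_parameter(self):
        out = fx.pump_and_leak(15.0, 2.2, P.psi_g, P, "astrocyte")
        assert out["J_pump"] == pytest.approx(P.j_pump0_g, rel=0.01)


class TestOxygen:
    def test_equilibrium_term_at_half_hb_saturation(self):
        # at O2_c = Hb.OP/2 the inverse-Hill term equals K_O2
        j = fx.oxygen_exchange_flux(0.0, P.hb_op / 2.0, P, "neuron")
        assert j == pytest.approx(P.ps_cap_vn * P.k_o2, rel=1e-12)

    def test_rest_influx_positive_and_small(self):
        j = fx.oxygen_exchange_flux(0.028, 7.0, P, "neuron")
        assert 0.0 < j < 0.1
        assert j == pytest.approx(1.66 * (0.0361 * (8.6 / 7.0 - 1.0) ** (-1 / 2.73) - 0.028), rel=1e-12)

    def test_oversaturated_capillary_rejected(self):
        with pytest.raises(ModelDomainError):
            fx.oxygen_exchange_flux(0.028, P.hb_op, P, "neuron")


class TestCapillary:
    def test_no_gradient_no_flow(self):
        s = {"O2_c": P.o2_a, "GLC_c": 4.5, "LAC_c": 0.55}
        assert fx.capillary_flows(s, 0.012, P)["J_O2_c"] == 0.0

    def test_zero_flow_zero_supply(self):
        s = {"O2_c": 7.0, "GLC_c": 4.5, "LAC_c": 0.55}
        out = fx.capillary_flows(s, 0.0, P)
        assert out["J_O2_c"] == out["J_GLC_c"] == out["J_LAC_c"] == 0.0

    def test_rest_oxygen_supply(self):
        s = {"O2_c": 7.0, "GLC_c": 4.5, "LAC_c": 0.55}
        out = fx.capillary_flows(s, 0.012, P)
        assert out["J_O2_c"] == pytest.approx(5.8909, rel=1e-4)
        assert out["O2c_bar"] == pytest.approx(2 * 7.0 - 8.35)


# ----------------------------------------------------------------------
# gates, currents, balloon
# ----------------------------------------------------------------------
class TestGates:
    def test_resting_gate_steady_states(self):
        g = fx.gate_kinetics(-73.0)
        assert g["n_inf"] == pytest.approx(0.02, abs=0.005)
        assert g["h_inf"] == pytest.approx(0.99, abs=0.005)

    def test_calcium_activation_midpoint(self):
        assert fx.gate_kinetics(-20.0)["m_Ca"] == pytest.approx(0.5)

    @pytest.mark.parametrize("psi,expected", [(-33.0, 1.0), (-34.0, None)])
    def test_removable_singularities(self, psi, expected):
        g = fx.gate_kinetics(psi)
        # alpha_m(-33) -> 1.0 by series expansion; continuity across the hole
        for eps in (1e-8, -1e-8):
            g_eps = fx.gate_kinetics(psi + eps)
            assert g_eps["m_inf"] == pytest.approx(g["m_inf"], rel=1e-5)
            assert g_eps["n_inf"] == pytest.approx(g["n_inf"], rel=1e-5)

    @given(st.floats(min_value=-120.0, max_value=60.0))
    def test_gates_bounded(self, psi):
        g = fx.gate_kinetics(psi)
        for key in ("m_inf", "h_inf", "n_inf", "m_Ca"):
            assert 0.0 <= g[key] <= 1.0
        assert g["tau_h"] > 0.0 and g["tau_n"] > 0.0


class TestCurrents:
    def _state(self, **over):
        y = {n: resting_state()[i] for n, i in ngv.STATE_INDEX.items()}
        y.update(over)
        return y

    def test_pump_current_zero_at_reference_sodium(self):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.hh_currents(self._state(Na_n=P.na_0_n), aden, P)
        assert out["I_pump"] == 0.0

    def test_potassium_currents_zero_at_reversal(self):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.hh_currents(self._state(psi_n=P.e_k), aden, P)
        assert out["I_K"] == pytest.approx(0.0, abs=1e-12)
        assert out["I_mAHP"] == pytest.approx(0.0, abs=1e-12)

    def test_mahp_half_activation_at_kd(self):
        aden = fx.adenylate_closure(2.2, P)
        out = fx.hh_currents(self._state(Ca=P.k_d, psi_n=-73.0), aden, P)
        assert out["I_mAHP"] == pytest.approx(0.5 * P.g_mahp * (-73.0 - P.e_k), rel=1e-12)


class TestBalloon:
    def test_baseline_balance(self):
        assert fx.balloon_outflow(P.vv_0, 0.0, P) == pytest.approx(P.f_0)

    def test_power_law_inflation(self):
        vv = P.vv_0 * 2.0 ** P.alpha_v
        assert fx.balloon_outflow(vv, 0.0, P) == pytest.approx(2.0 * P.f_0)

    def test_implicit_pair_fixed_point_at_baseline(self):
        f_out, dvv = fx.resolve_balloon(P.vv_0, P.f_0, P)
        assert f_out == pytest.approx(P.f_0, rel=1e-12)
        assert dvv == pytest.approx(0.0, abs=1e-15)

    @given(st.floats(min_value=0.5, max_value=2.0), st.floats(min_value=0.0, max_value=0.05))
    def test_resolved_outflow_satisfies_the_printed_law(self, v_rel, f_in):
        vv = P.vv_0 * v_rel
        f_out, dvv = fx.resolve_balloon(vv, f_in, P)
        assert f_out == pytest.approx(fx.balloon_outflow(vv, dvv, P), rel=1e-10)

    def test_collapsed_balloon_rejected(self):
        with pytest.raises(ModelDomainError):
            fx.balloon_outflow(0.0, 0.0, P)
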