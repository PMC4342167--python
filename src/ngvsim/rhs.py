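"""Assembly of the 33 governing equations.

Two equivalent code paths are provided:

* :func:`compute_derivatives` assembles the state derivative from the named
  flux functions in :mod:`ngvsim.fluxes`.  It is the reference path, used by
  the steady-state solver and exposed for inspection and testing.
* :func:`make_fast_rhs` returns a hand-inlined scalar closure evaluating the
  identical expressions with plain ``math`` calls; it is what the stiff
  integrator calls.  Equality of the two paths to near machine precision is
  enforced by the test suite.

Volume bookkeeping: cell-interior fluxes are per cell volume, capillary
balances convert cell fluxes with the volume ratios ``r_cn``/``r_cg``/
``r_ce``, extracellular balances with ``r_en``/``r_eg``; the NADH balances
rescale by the cytosolic (1-xi) and mitochondrial (xi) sub-volumes; the ATP
balances carry the adenylate buffering factor (1 - dAMP/dATP)^-1.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping

import numpy as np

from . import fluxes as fx
from .errors import ModelDomainError
from .params import ParameterSet
from .state import N_STATES, STATE_INDEX

__all__ = ["compute_derivatives", "make_fast_rhs", "clamp_indices"]


def clamp_indices(clamped_states: Iterable[str]) -> tuple[int, ...]:
    """Translate state names into indices, rejecting unknown names."""
    idx = []
    for name in clamped_states:
        if name not in STATE_INDEX:
            raise ModelDomainError(f"unknown state name {name!r} in clamp set")
        idx.append(STATE_INDEX[name])
    return tuple(sorted(idx))


def compute_derivatives(
    t: float,
    state: np.ndarray,
    inputs: Mapping[str, float],
    params: ParameterSet,
    clamp_mask: Iterable[str] = (),
) -> np.ndarray:
    """Right-hand side of the full system at one state.

    ``inputs`` carries the external drives: ``f_exc`` (Hz), ``F_in`` (s^-1)
    and ``g_bar_total`` (= N_exc * g_bar, mS cm^-2 s).  The synaptic current,
    sodium drives and balloon outflow are derived internally so that the
    reference and fast paths share one definition.  Clamped states get a zero
    derivative.
    """
    y = np.asarray(state, dtype=float)
    p = params
    f_exc = float(inputs.get("f_exc", 0.0))
    f_in = float(inputs.get("F_in", p.f_0))
    g_bar_total = float(inputs.get("g_bar_total", 0.0))
    e_ampa = float(inputs.get("E_AMPA", 0.0))

    fl = fx.evaluate_fluxes(y, p, f_exc=f_exc, f_in=f_in, g_bar_total=g_bar_total)
    s = {n: y[i] for n, i in STATE_INDEX.items()}
    aden_n = fx.adenylate_closure(s["ATP_n"], p)
    aden_g = fx.adenylate_closure(s["ATP_g"], p)

    i_syn = fl["g_exc"] * (e_ampa - s["psi_n"])
    j_stim_n = p.sm_vn / p.faraday * ((2.0 / 3.0) * i_syn - fl["I_Na"])
    j_stim_g = 3.0 * inputs.get("delta_glut", 2.25e-5) * inputs.get("n_exc", 1500.0) * f_exc
    gk = fx.gate_kinetics(s["psi_n"])
    f_out, dvv = fx.resolve_balloon(s["Vv"], f_in, p)

    dy = np.empty(N_STATES)
    ix = STATE_INDEX
    dy[ix["Na_n"]] = fl["J_leak_Na_n"] - 3.0 * fl["J_pump_n"] + j_stim_n
    dy[ix["Na_g"]] = fl["J_leak_Na_g"] - 3.0 * fl["J_pump_g"] + j_stim_g
    dy[ix["GLC_n"]] = fl["J_GLC_en"] - fl["J_HKPFK_n"]
    dy[ix["GLC_g"]] = fl["J_GLC_cg"] + fl["J_GLC_eg"] - fl["J_HKPFK_g"]
    dy[ix["GAP_n"]] = 2.0 * fl["J_HKPFK_n"] - fl["J_PGK_n"]
    dy[ix["GAP_g"]] = 2.0 * fl["J_HKPFK_g"] - fl["J_PGK_g"]
    dy[ix["PEP_n"]] = fl["J_PGK_n"] - fl["J_PK_n"]
    dy[ix["PEP_g"]] = fl["J_PGK_g"] - fl["J_PK_g"]
    dy[ix["PYR_n"]] = fl["J_PK_n"] - fl["J_LDH_n"] - fl["J_mito_in_n"]
    dy[ix["PYR_g"]] = fl["J_PK_g"] - fl["J_LDH_g"] - fl["J_mito_in_g"]
    dy[ix["LAC_n"]] = fl["J_LDH_n"] - fl["J_LAC_ne"]
    dy[ix["LAC_g"]] = fl["J_LDH_g"] - fl["J_LAC_ge"] - fl["J_LAC_gc"]
    dy[ix["NADH_cyto_n"]] = (fl["J_PGK_n"] - fl["J_LDH_n"] - fl["J_shuttle_n"]) / (1.0 - p.xi)
    dy[ix["NADH_cyto_g"]] = (fl["J_PGK_g"] - fl["J_LDH_g"] - fl["J_shuttle_g"]) / (1.0 - p.xi)
    dy[ix["NADH_mito_n"]] = (4.0 * fl["J_mito_in_n"] - fl["J_mito_out_n"] + fl["J_shuttle_n"]) / p.xi
    dy[ix["NADH_mito_g"]] = (4.0 * fl["J_mito_in_g"] - fl["J_mito_out_g"] + fl["J_shuttle_g"]) / p.xi
    dy[ix["ATP_n"]] = (
        -2.0 * fl["J_HKPFK_n"] + fl["J_PGK_n"] + fl["J_PK_n"]
        - p.j_atpases_n - fl["J_pump_n"] + 3.6 * fl["J_mito_out_n"] + fl["J_CK_n"]
    ) / (1.0 - aden_n.damp_datp)
    dy[ix["ATP_g"]] = (
        -2.0 * fl["J_HKPFK_g"] + fl["J_PGK_g"] + fl["J_PK_g"]
        - p.j_atpases_g - 1.75 * fl["J_pump_g"] + 0.75 * p.j_pump0_g
        + 3.6 * fl["J_mito_out_g"] + fl["J_CK_g"]
    ) / (1.0 - aden_g.damp_datp)
    dy[ix["PCr_n"]] = -fl["J_CK_n"]
    dy[ix["PCr_g"]] = -fl["J_CK_g"]
    dy[ix["O2_n"]] = fl["J_O2mc_n"] - 0.6 * fl["J_mito_out_n"]
    dy[ix["O2_g"]] = fl["J_O2mc_g"] - 0.6 * fl["J_mito_out_g"]
    dy[ix["O2_c"]] = fl["J_O2_c"] - fl["J_O2mc_n"] / p.r_cn - fl["J_O2mc_g"] / p.r_cg
    dy[ix["GLC_c"]] = fl["J_GLC_c"] - fl["J_GLC_ce"] / p.r_ce - fl["J_GLC_cg"] / p.r_cg
    dy[ix["LAC_c"]] = fl["J_LAC_c"] + fl["J_LAC_ec"] / p.r_ce + fl["J_LAC_gc"] / p.r_cg
    dy[ix["Vv"]] = dvv
    dy[ix["dHb"]] = f_in * (p.o2_a - fl["O2c_bar"]) - f_out * s["dHb"] / s["Vv"]
    dy[ix["GLC_e"]] = fl["J_GLC_ce"] - fl["J_GLC_eg"] / p.r_eg - fl["J_GLC_en"] / p.r_en
    dy[ix["LAC_e"]] = fl["J_LAC_ne"] / p.r_en + fl["J_LAC_ge"] / p.r_eg - fl["J_LAC_ec"]
    dy[ix["psi_n"]] = (
        -fl["I_L"] - fl["I_Na"] - fl["I_K"] - fl["I_Ca"] - fl["I_mAHP"]
        - fl["I_pump"] + i_syn
    ) / p.c_m
    dy[ix["h"]] = p.phi_h / gk["tau_h"] * (gk["h_inf"] - s["h"])
    dy[ix["n_gate"]] = p.phi_n / gk["tau_n"] * (gk["n_inf"] - s["n_gate"])
    dy[ix["Ca"]] = -p.sm_vn / p.faraday * fl["I_Ca"] - (s["Ca"] - p.ca_0) / p.tau_ca

    for i in clamp_indices(clamp_mask):
        dy[i] = 0.0
    return dy


def make_fast_rhs(
    params: ParameterSet,
    stimulus,
    flow: Callable[[float], float] | None,
    clamp: Iterable[str] = (),
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the scalar right-hand side used by the integrator.

    ``stimulus`` must expose ``rate(t) -> Hz`` and the constants
    ``n_exc * g_bar``, ``delta_glut`` and ``e_ampa``; ``flow`` maps time to
    blood inflow (``None`` means constant baseline flow).  ``clamp`` lists
    state names whose derivatives are forced to zero.
    """
    p = params
    exp, log, sqrt = math.exp, math.log, math.sqrt
    # locals for speed
    A, qak, Ntot, Ctot = p.a_tot, p.q_ak, p.n_tot, p.c_tot
    F, rt_f = p.faraday, p.rt_f
    sv_n_F, sv_g_F = p.sm_vn / F, p.sm_vg / F
    r_cn, r_cg, r_ce, r_en, r_eg = p.r_cn, p.r_cg, p.r_ce, p.r_en, p.r_eg
    one_m_xi, xi = 1.0 - p.xi, p.xi
    g_bar_total = stimulus.n_exc * stimulus.g_bar
    delta3 = 3.0 * stimulus.delta_glut * stimulus.n_exc
    e_ampa = stimulus.e_ampa
    rate = stimulus.rate
    f0 = p.f_0
    clamp_ix = clamp_indices(clamp)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        (Na_n, Na_g, GLC_n, GLC_g, GAP_n, GAP_g, PEP_n, PEP_g, PYR_n, PYR_g,
         LAC_n, LAC_g, NADHc_n, NADHc_g, NADHm_n, NADHm_g, ATP_n, ATP_g,
         PCr_n, PCr_g, O2_n, O2_g, O2_c, GLC_c, LAC_c, Vv, dHb, GLC_e, LAC_e,
         psi, h, ng, Ca) = y

        # adenylate closure
        u_n = qak * qak + 4.0 * qak * (A / ATP_n - 1.0)
        su_n = sqrt(u_n)
        ADP_n = ATP_n / 2.0 * (-qak + su_n)
        dA_n = -1.0 + qak / 2.0 - su_n / 2.0 + qak * A / (ATP_n * su_n)
        u_g = qak * qak + 4.0 * qak * (A / ATP_g - 1.0)
        su_g = sqrt(u_g)
        ADP_g = ATP_g / 2.0 * (-qak + su_g)
        dA_g = -1.0 + qak / 2.0 - su_g / 2.0 + qak * A / (ATP_g * su_g)

        # stimulus and flow
        fe = rate(t)
        Fin = f0 if flow is None else flow(t)

        # gating
        x_m = psi + 33.0
        a_m = 1.0 + 0.05 * x_m if abs(x_m) < 1e-6 else -0.1 * x_m / (exp(-0.1 * x_m) - 1.0)
        b_m = 4.0 * exp(-(psi + 58.0) / 12.0)
        a_h = 0.07 * exp(-(psi + 50.0) / 10.0)
        b_h = 1.0 / (exp(-0.1 * (psi + 20.0)) + 1.0)
        x_n = psi + 34.0
        a_n = 0.1 + 0.005 * x_n if abs(x_n) < 1e-6 else -0.01 * x_n / (exp(-0.1 * x_n) - 1.0)
        b_n = 0.125 * exp(-(psi + 44.0) / 25.0)
        m_inf = a_m / (a_m + b_m)
        h_inf = a_h / (a_h + b_h)
        n_inf = a_n / (a_n + b_n)
        tau_h = 1e-3 / (a_h + b_h)
        tau_n = 1e-3 / (a_n + b_n)
        m_ca = 1.0 / (1.0 + exp(-(psi + 20.0) / 9.0))

        # currents
        E_Na = rt_f * log(p.na_e / Na_n)
        E_L = (p.g_k_pas * p.e_k + p.g_na_n * E_Na) / (p.g_k_pas + p.g_na_n)
        I_L = p.g_l * (psi - E_L)
        I_Na = p.g_na * m_inf * m_inf * m_inf * h * (psi - E_Na)
        I_K = p.g_k * ng * ng * ng * ng * (psi - p.e_k)
        I_Ca = p.g_ca * m_ca * m_ca * (psi - p.e_ca)
        I_mAHP = p.g_mahp * Ca / (Ca + p.k_d) * (psi - p.e_k)
        I_pump = F * p.k_pump_n * ATP_n * (Na_n - p.na_0_n) / (1.0 + ATP_n / p.k_m_pump)
        g_exc = g_bar_total * fe
        I_syn = g_exc * (e_ampa - psi)

        # pumps, leaks, drives
        J_pump_n = p.sm_vn * p.k_pump_n * ATP_n * Na_n / (1.0 + ATP_n / p.k_m_pump)
        J_pump_g = p.sm_vg * p.k_pump_g * ATP_g * Na_g / (1.0 + ATP_g / p.k_m_pump)
        J_leak_n = sv_n_F * p.g_na_n * (E_Na - psi)
        J_leak_g = sv_g_F * p.g_na_g * (rt_f * log(p.na_e / Na_g) - p.psi_g)
        Jstim_n = sv_n_F * ((2.0 / 3.0) * I_syn - I_Na)
        Jstim_g = delta3 * fe

        # glucose pathway
        J_glc_en = p.tmax_glc_en * (GLC_e / (GLC_e + p.kt_glc_en) - GLC_n / (GLC_n + p.kt_glc_en))
        J_glc_eg = p.tmax_glc_eg * (GLC_e / (GLC_e + p.kt_glc_eg) - GLC_g / (GLC_g + p.kt_glc_eg))
        J_glc_cg = p.tmax_glc_cg * (GLC_c / (GLC_c + p.kt_glc_cg) - GLC_g / (GLC_g + p.kt_glc_cg))
        J_glc_ce = p.tmax_glc_ce * (GLC_c / (GLC_c + p.kt_glc_ce) - GLC_e / (GLC_e + p.kt_glc_ce))
        inh_n = 1.0 + (ATP_n / p.k_i_atp) ** p.n_h
        inh_g = 1.0 + (ATP_g / p.k_i_atp) ** p.n_h
        J_hk_n = p.k_hkpfk_n * ATP_n * GLC_n / (GLC_n + p.k_g) / inh_n
        J_hk_g = p.k_hkpfk_g * ATP_g * GLC_g / (GLC_g + p.k_g) / inh_g
        J_pgk_n = p.k_pgk_n * GAP_n * ADP_n * (Ntot - NADHc_n) / NADHc_n
        J_pgk_g = p.k_pgk_g * GAP_g * ADP_g * (Ntot - NADHc_g) / NADHc_g
        J_pk_n = p.k_pk_n * PEP_n * ADP_n
        J_pk_g = p.k_pk_g * PEP_g * ADP_g
        J_ldh_n = p.kp_ldh_n * PYR_n * NADHc_n - p.km_ldh_n * LAC_n * (Ntot - NADHc_n)
        J_ldh_g = p.kp_ldh_g * PYR_g * NADHc_g - p.km_ldh_g * LAC_g * (Ntot - NADHc_g)

        # lactate carriers
        J_lac_ne = p.tmax_lac_ne * (LAC_n / (LAC_n + p.kt_lac_ne) - LAC_e / (LAC_e + p.kt_lac_ne))
        J_lac_ge = p.tmax_lac_ge * (LAC_g / (LAC_g + p.kt_lac_ge) - LAC_e / (LAC_e + p.kt_lac_ge))
        J_lac_gc = p.tmax_lac_gc * (LAC_g / (LAC_g + p.kt_lac_gc) - LAC_c / (LAC_c + p.kt_lac_gc))
        J_lac_ec = p.tmax_lac_ec * (LAC_e / (LAC_e + p.kt_lac_ec) - LAC_c / (LAC_c + p.kt_lac_ec))

        # mitochondria and shuttles
        nad_m_n = Ntot - NADHm_n
        nad_m_g = Ntot - NADHm_g
        J_min_n = p.vmax_in_n * PYR_n / (PYR_n + p.k_m_mito) * nad_m_n / (nad_m_n + p.k_m_nad_n)
        J_min_g = p.vmax_in_g * PYR_g / (PYR_g + p.k_m_mito) * nad_m_g / (nad_m_g + p.k_m_nad_g)
        J_mout_n = (p.vmax_out_n * O2_n / (O2_n + p.k_o2_mito)
                    * ADP_n / (ADP_n + p.k_m_adp_n) * NADHm_n / (NADHm_n + p.k_m_nadh_n))
        J_mout_g = (p.vmax_out_g * O2_g / (O2_g + p.k_o2_mito)
                    * ADP_g / (ADP_g + p.k_m_adp_g) * NADHm_g / (NADHm_g + p.k_m_nadh_g))
        rm_n = NADHc_n / (Ntot - NADHc_n)
        rp_n = nad_m_n / NADHm_n
        rm_g = NADHc_g / (Ntot - NADHc_g)
        rp_g = nad_m_g / NADHm_g
        J_sh_n = p.t_nadh_n * rm_n / (rm_n + p.m_cyto_n) * rp_n / (rp_n + p.m_mito_n)
        J_sh_g = p.t_nadh_g * rm_g / (rm_g + p.m_cyto_g) * rp_g / (rp_g + p.m_mito_g)
        J_ck_n = p.kp_ck_n * ADP_n * PCr_n - p.km_ck_n * ATP_n * (Ctot - PCr_n)
        J_ck_g = p.kp_ck_g * ADP_g * PCr_g - p.km_ck_g * ATP_g * (Ctot - PCr_g)

        # oxygen exchange and capillary advection
        eq_o2 = p.k_o2 * (p.hb_op / O2_c - 1.0) ** (-1.0 / p.n_hb)
        J_o2_n = p.ps_cap_vn * (eq_o2 - O2_n)
        J_o2_g = p.ps_cap_vg * (eq_o2 - O2_g)
        adv = 2.0 * Fin / p.v_cap
        J_o2_c = adv * (p.o2_a - O2_c)
        J_glc_c = adv * (p.glc_a - GLC_c)
        J_lac_c = adv * (p.lac_a - LAC_c)
        O2c_bar = 2.0 * O2_c - p.o2_a

        # balloon (implicit outflow)
        v = Vv / p.vv_0
        a_b = f0 * p.tau_v / p.vv_0 / sqrt(v)
        F_out = (f0 * v * v + a_b * Fin) / (1.0 + a_b) if p.alpha_v == 0.5 else (
            (f0 * v ** (1.0 / p.alpha_v) + a_b * Fin) / (1.0 + a_b)
        )

        dy = np.empty(33)
        dy[0] = J_leak_n - 3.0 * J_pump_n + Jstim_n
        dy[1] = J_leak_g - 3.0 * J_pump_g + Jstim_g
        dy[2] = J_glc_en - J_hk_n
        dy[3] = J_glc_cg + J_glc_eg - J_hk_g
        dy[4] = 2.0 * J_hk_n - J_pgk_n
        dy[5] = 2.0 * J_hk_g - J_pgk_g
        dy[6] = J_pgk_n - J_pk_n
        dy[7] = J_pgk_g - J_pk_g
        dy[8] = J_pk_n - J_ldh_n - J_min_n
        dy[9] = J_pk_g - J_ldh_g - J_min_g
        dy[10] = J_ldh_n - J_lac_ne
        dy[11] = J_ldh_g - J_lac_ge - J_lac_gc
        dy[12] = (J_pgk_n - J_ldh_n - J_sh_n) / one_m_xi
        dy[13] = (J_pgk_g - J_ldh_g - J_sh_g) / one_m_xi
        dy[14] = (4.0 * J_min_n - J_mout_n + J_sh_n) / xi
        dy[15] = (4.0 * J_min_g - J_mout_g + J_sh_g) / xi
        dy[16] = (-2.0 * J_hk_n + J_pgk_n + J_pk_n - p.j_atpases_n - J_pump_n
                  + 3.6 * J_mout_n + J_ck_n) / (1.0 - dA_n)
        dy[17] = (-2.0 * J_hk_g + J_pgk_g + J_pk_g - p.j_atpases_g
                  - 1.75 * J_pump_g + 0.75 * p.j_pump0_g
                  + 3.6 * J_mout_g + J_ck_g) / (1.0 - dA_g)
        dy[18] = -J_ck_n
        dy[19] = -J_ck_g
        dy[20] = J_o2_n - 0.6 * J_mout_n
        dy[21] = J_o2_g - 0.6 * J_mout_g
        dy[22] = J_o2_c - J_o2_n / r_cn - J_o2_g / r_cg
        dy[23] = J_glc_c - J_glc_ce / r_ce - J_glc_cg / r_cg
        dy[24] = J_lac_c + J_lac_ec / r_ce + J_lac_gc / r_cg
        dy[25] = Fin - F_out
        dy[26] = Fin * (p.o2_a - O2c_bar) - F_out * dHb / Vv
        dy[27] = J_glc_ce - J_glc_eg / r_eg - J_glc_en / r_en
        dy[28] = J_lac_ne / r_en + J_lac_ge / r_eg - J_lac_ec
        dy[29] = (-I_L - I_Na - I_K - I_Ca - I_mAHP - I_pump + I_syn) / p.c_m
        dy[30] = p.phi_h / tau_h * (h_inf - h)
        dy[31] = p.phi_n / tau_n * (n_inf - ng)
        dy[32] = -sv_n_F * I_Ca - (Ca - p.ca_0) / p.tau_ca
        for i in clamp_ix:
            dy[i] = 0.0
        return dy

    return rhs
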