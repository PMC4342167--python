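"""Reaction rates, carrier transports and membrane currents of the NGV model.

Each public function evaluates one kinetic expression; all of them accept
scalars or NumPy arrays and broadcast elementwise, so the same code path
serves single-state evaluation and whole-trajectory post-processing.
``evaluate_fluxes`` assembles the complete flux vector at a state.

Sign conventions: a two-compartment transport ``J_X_ab`` is positive when X
moves from compartment ``a`` to compartment ``b``. Membrane currents follow
the outward-positive electrophysiology convention (an inward sodium current
is negative); the synaptic current ``I_syn`` is inward-positive so that it
depolarizes and drives sodium entry with a plus sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ModelDomainError
from .params import ParameterSet
from .state import STATE_INDEX

__all__ = [
    "DerivedAdenylate",
    "adenylate_closure",
    "carrier_flux",
    "glycolysis_fluxes",
    "ldh_flux",
    "mito_fluxes",
    "nadh_shuttle_flux",
    "creatine_kinase_flux",
    "pump_and_leak",
    "oxygen_exchange_flux",
    "capillary_flows",
    "gate_kinetics",
    "hh_currents",
    "balloon_outflow",
    "evaluate_fluxes",
]

_COMPARTMENTS = ("neuron", "astrocyte")


def _suffix(compartment: str) -> str:
    if compartment in ("neuron", "n"):
        return "n"
    if compartment in ("astrocyte", "glia", "g"):
        return "g"
    raise ModelDomainError(f"unknown compartment {compartment!r}")


# ----------------------------------------------------------------------
# adenylate pool closure
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DerivedAdenylate:
    """ADP and AMP implied by ATP through the adenylate-kinase equilibrium."""

    adp: np.ndarray | float
    amp: np.ndarray | float
    damp_datp: np.ndarray | float


def adenylate_closure(atp, params: ParameterSet) -> DerivedAdenylate:
    """Close the adenine pool: given ATP, return ADP, AMP and dAMP/dATP.

    ADP follows from the adenylate-kinase equilibrium AMP*ATP = q_AK*ADP^2
    combined with the pool constraint ATP+ADP+AMP = A; AMP is the remainder.
    The derivative dAMP/dATP corrects the ATP balance for the buffering by
    the other two nucleotides.
    """
    atp = np.asarray(atp, dtype=float)
    a, q = params.a_tot, params.q_ak
    if np.any(atp <= 0.0) or np.any(atp > a):
        raise ModelDomainError(f"ATP must lie in (0, A={a}]; got {atp}")
    u = q * q + 4.0 * q * (a / atp - 1.0)
    su = np.sqrt(u)
    adp = atp / 2.0 * (-q + su)
    amp = a - atp - adp
    damp_datp = -1.0 + q / 2.0 - su / 2.0 + q * a / (atp * su)
    if atp.ndim == 0:
        return DerivedAdenylate(float(adp), float(amp), float(damp_datp))
    return DerivedAdenylate(adp, amp, damp_datp)


# ----------------------------------------------------------------------
# carriers and enzymes
# ----------------------------------------------------------------------
def carrier_flux(src_conc, dst_conc, tmax: float, kt: float):
    """Reversible facilitated-diffusion carrier (shared by glucose and lactate).

    J = Tmax * (s/(s+Kt) - d/(d+Kt)); antisymmetric in its endpoints and
    positive when the source side is more loaded.
    """
    src = np.asarray(src_conc, dtype=float)
    dst = np.asarray(dst_conc, dtype=float)
    if np.any(src < 0.0) or np.any(dst < 0.0):
        raise ModelDomainError("carrier concentrations must be non-negative")
    if tmax <= 0.0 or kt <= 0.0:
        raise ModelDomainError("carrier Tmax and Kt must be positive")
    out = tmax * (src / (src + kt) - dst / (dst + kt))
    return float(out) if out.ndim == 0 else out


def glycolysis_fluxes(
    state: Mapping[str, float] | np.ndarray,
    adenylate: DerivedAdenylate,
    params: ParameterSet,
    compartment: str,
) -> dict:
    """Lumped glycolysis: HK-PFK entry, PGK (NADH producing) and PK steps."""
    s = _as_mapping(state)
    x = _suffix(compartment)
    atp = s[f"ATP_{x}"]
    glc = s[f"GLC_{x}"]
    gap = s[f"GAP_{x}"]
    pep = s[f"PEP_{x}"]
    nadh = s[f"NADH_cyto_{x}"]
    if np.any(np.asarray(nadh) <= 0.0):
        raise ModelDomainError("cytosolic NADH must be positive for the PGK step")
    k_hk = getattr(params, f"k_hkpfk_{x}")
    j_hkpfk = (
        k_hk * atp * glc / (glc + params.k_g)
        / (1.0 + (atp / params.k_i_atp) ** params.n_h)
    )
    j_pgk = (
        getattr(params, f"k_pgk_{x}") * gap * adenylate.adp
        * (params.n_tot - nadh) / nadh
    )
    j_pk = getattr(params, f"k_pk_{x}") * pep * adenylate.adp
    return {"J_HKPFK": j_hkpfk, "J_PGK": j_pgk, "J_PK": j_pk}


def ldh_flux(pyr, nadh_cyto, lac, params: ParameterSet, compartment: str):
    """Lactate dehydrogenase net flux (positive: pyruvate + NADH -> lactate).

    Mass-action in both directions: forward k+ * PYR * NADH_cyto, reverse
    k- * LAC * NAD+ with NAD+ = N - NADH_cyto.
    """
    x = _suffix(compartment)
    pyr = np.asarray(pyr, dtype=float)
    nadh = np.asarray(nadh_cyto, dtype=float)
    lac = np.asarray(lac, dtype=float)
    if np.any(pyr < 0.0) or np.any(nadh < 0.0) or np.any(lac < 0.0):
        raise ModelDomainError("LDH substrates must be non-negative")
    out = (
        getattr(params, f"kp_ldh_{x}") * pyr * nadh
        - getattr(params, f"km_ldh_{x}") * lac * (params.n_tot - nadh)
    )
    return float(out) if out.ndim == 0 else out


def mito_fluxes(
    state: Mapping[str, float] | np.ndarray,
    adenylate: DerivedAdenylate,
    params: ParameterSet,
    compartment: str,
) -> dict:
    """Mitochondrial NADH production (TCA input) and consumption (ETC output).

    The TCA step yields 4 NADH per pyruvate and saturates in pyruvate and
    free mitochondrial NAD+; the electron-transport step consumes NADH and
    oxygen under ADP control.
    """
    s = _as_mapping(state)
    x = _suffix(compartment)
    pyr = s[f"PYR_{x}"]
    nadh_m = s[f"NADH_mito_{x}"]
    o2 = s[f"O2_{x}"]
    nad_m = params.n_tot - nadh_m
    j_in = (
        getattr(params, f"vmax_in_{x}")
        * pyr / (pyr + params.k_m_mito)
        * nad_m / (nad_m + getattr(params, f"k_m_nad_{x}"))
    )
    j_out = (
        getattr(params, f"vmax_out_{x}")
        * o2 / (o2 + params.k_o2_mito)
        * adenylate.adp / (adenylate.adp + getattr(params, f"k_m_adp_{x}"))
        * nadh_m / (nadh_m + getattr(params, f"k_m_nadh_{x}"))
    )
    return {"J_mito_in": j_in, "J_mito_out": j_out}


def nadh_shuttle_flux(nadh_cyto, nadh_mito, params: ParameterSet, compartment: str):
    """Malate-aspartate-like shuttle moving reducing equivalents into mitochondria.

    Saturating in the cytosolic redox ratio R- = NADH/(N-NADH) and in the
    mitochondrial oxidation ratio R+ = (N-NADH)/NADH.
    """
    x = _suffix(compartment)
    n = params.n_tot
    nadh_c = np.asarray(nadh_cyto, dtype=float)
    nadh_m = np.asarray(nadh_mito, dtype=float)
    if np.any(nadh_c <= 0.0) or np.any(nadh_c >= n) or np.any(nadh_m <= 0.0) or np.any(nadh_m >= n):
        raise ModelDomainError(f"NADH pools must lie strictly inside (0, N={n})")
    r_minus = nadh_c / (n - nadh_c)
    r_plus = (n - nadh_m) / nadh_m
    out = (
        getattr(params, f"t_nadh_{x}")
        * r_minus / (r_minus + getattr(params, f"m_cyto_{x}"))
        * r_plus / (r_plus + getattr(params, f"m_mito_{x}"))
    )
    return float(out) if out.ndim == 0 else out


def creatine_kinase_flux(adp, atp, pcr, params: ParameterSet, compartment: str):
    """Creatine kinase net flux (positive: PCr + ADP -> ATP + Cr)."""
    x = _suffix(compartment)
    pcr = np.asarray(pcr, dtype=float)
    if np.any(pcr < 0.0) or np.any(pcr > params.c_tot):
        raise ModelDomainError(f"PCr must lie in [0, C={params.c_tot}]")
    out = (
        getattr(params, f"kp_ck_{x}") * np.asarray(adp, float) * pcr
        - getattr(params, f"km_ck_{x}") * np.asarray(atp, float) * (params.c_tot - pcr)
    )
    return float(out) if out.ndim == 0 else out


def pump_and_leak(na, atp, psi, params: ParameterSet, compartment: str) -> dict:
    """Na,K-ATPase extrusion and passive sodium leak of one cell type.

    The leak is driven by the sodium electrochemical gradient (Nernst term
    minus membrane voltage); the pump consumes one ATP per cycle and extrudes
    three sodium ions (the factor 3 is applied in the sodium balance).  For
    the astrocyte the membrane voltage is the fixed parameter ``psi_g``.
    """
    x = _suffix(compartment)
    na = np.asarray(na, dtype=float)
    if np.any(na <= 0.0):
        raise ModelDomainError("intracellular sodium must be positive")
    sm_v = getattr(params, f"sm_v{x}")
    g_na_leak = getattr(params, f"g_na_{x}")
    k_pump = getattr(params, f"k_pump_{x}")
    j_leak = (
        sm_v / params.faraday * g_na_leak
        * (params.rt_f * np.log(params.na_e / na) - np.asarray(psi, float))
    )
    j_pump = (
        sm_v * k_pump * np.asarray(atp, float) * na
        / (1.0 + np.asarray(atp, float) / params.k_m_pump)
    )
    if np.ndim(j_pump) == 0:
        return {"J_pump": float(j_pump), "J_leak_Na": float(j_leak)}
    return {"J_pump": j_pump, "J_leak_Na": j_leak}


def oxygen_exchange_flux(o2_x, o2_c, params: ParameterSet, compartment: str):
    """Oxygen transfer from capillary blood into one cell type.

    The driving term is the plasma oxygen concentration in equilibrium with
    hemoglobin at capillary content ``O2_c`` (inverse Hill relation), minus
    the intracellular oxygen.
    """
    x = _suffix(compartment)
    o2_c = np.asarray(o2_c, dtype=float)
    if np.any(o2_c <= 0.0) or np.any(o2_c >= params.hb_op):
        raise ModelDomainError(
            f"capillary O2 must lie in (0, Hb.OP={params.hb_op}) for Hb saturation"
        )
    eq = params.k_o2 * (params.hb_op / o2_c - 1.0) ** (-1.0 / params.n_hb)
    out = getattr(params, f"ps_cap_v{x}") * (eq - np.asarray(o2_x, float))
    return float(out) if out.ndim == 0 else out


def capillary_flows(
    state: Mapping[str, float] | np.ndarray, f_in, params: ParameterSet
) -> dict:
    """Advective supply of O2, glucose and lactate by the blood flow.

    Each follows 2*F_in/V_cap * (arterial - capillary); the mean/end-capillary
    oxygen ``O2c_bar`` = 2*O2_c - O2_a treats the capillary content as the
    arterial/end-capillary average.
    """
    s = _as_mapping(state)
    f_in = np.asarray(f_in, dtype=float)
    if np.any(f_in < 0.0):
        raise ModelDomainError("blood inflow must be non-negative")
    scale = 2.0 * f_in / params.v_cap
    out = {
        "J_O2_c": scale * (params.o2_a - s["O2_c"]),
        "J_GLC_c": scale * (params.glc_a - s["GLC_c"]),
        "J_LAC_c": scale * (params.lac_a - s["LAC_c"]),
        "O2c_bar": 2.0 * s["O2_c"] - params.o2_a,
    }
    if f_in.ndim == 0 and np.ndim(out["O2c_bar"]) == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


# ----------------------------------------------------------------------
# Hodgkin-Huxley machinery
# ----------------------------------------------------------------------
def gate_kinetics(psi) -> dict:
    """Steady states, time constants and instantaneous activations of the gates.

    Rate constants are in ms^-1 as is conventional; time constants are
    converted to seconds.  The removable singularities of alpha_m at -33 mV
    and alpha_n at -34 mV are evaluated by their analytic limits.
    """
    psi = np.asarray(psi, dtype=float)
    x_m = psi + 33.0
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        a_m = np.where(
            np.abs(x_m) < 1e-6,
            1.0 + 0.05 * x_m,  # first-order expansion at the singular voltage
            -0.1 * x_m / np.expm1(-0.1 * x_m),
        )
        x_n = psi + 34.0
        a_n = np.where(
            np.abs(x_n) < 1e-6,
            0.1 + 0.005 * x_n,
            -0.01 * x_n / np.expm1(-0.1 * x_n),
        )
    b_m = 4.0 * np.exp(-(psi + 58.0) / 12.0)
    a_h = 0.07 * np.exp(-(psi + 50.0) / 10.0)
    b_h = 1.0 / (np.exp(-0.1 * (psi + 20.0)) + 1.0)
    b_n = 0.125 * np.exp(-(psi + 44.0) / 25.0)
    out = {
        "m_inf": a_m / (a_m + b_m),
        "h_inf": a_h / (a_h + b_h),
        "n_inf": a_n / (a_n + b_n),
        "tau_h": 1e-3 / (a_h + b_h),
        "tau_n": 1e-3 / (a_n + b_n),
        "m_Ca": 1.0 / (1.0 + np.exp(-(psi + 20.0) / 9.0)),
    }
    if psi.ndim == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


def hh_currents(
    state: Mapping[str, float] | np.ndarray,
    adenylate: DerivedAdenylate,
    params: ParameterSet,
) -> dict:
    """All neuronal membrane currents (outward-positive, mV*mS*cm^-2).

    The sodium reversal potential is recomputed from intracellular sodium at
    every evaluation; the leak reversal E_L re-balances the passive potassium
    and sodium conductances around it.  The sodium current uses instantaneous
    activation m_inf^3.  The pump current counts only the sodium excess over
    its reference value, baseline pumping being absorbed into E_L.
    """
    s = _as_mapping(state)
    na = np.asarray(s["Na_n"], dtype=float)
    if np.any(na <= 0.0):
        raise ModelDomainError("neuronal sodium must be positive")
    psi = s["psi_n"]
    g = gate_kinetics(psi)
    e_na = params.rt_f * np.log(params.na_e / na)
    e_l = (params.g_k_pas * params.e_k + params.g_na_n * e_na) / (
        params.g_k_pas + params.g_na_n
    )
    out = {
        "I_L": params.g_l * (psi - e_l),
        "I_Na": params.g_na * g["m_inf"] ** 3 * s["h"] * (psi - e_na),
        "I_K": params.g_k * s["n_gate"] ** 4 * (psi - params.e_k),
        "I_Ca": params.g_ca * g["m_Ca"] ** 2 * (psi - params.e_ca),
        "I_mAHP": params.g_mahp * s["Ca"] / (s["Ca"] + params.k_d) * (psi - params.e_k),
        "I_pump": (
            params.faraday * params.k_pump_n * s["ATP_n"] * (na - params.na_0_n)
            / (1.0 + s["ATP_n"] / params.k_m_pump)
        ),
    }
    if na.ndim == 0 and np.ndim(psi) == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


def balloon_outflow(vv, dvv_dt, params: ParameterSet):
    """Outflow of the venous balloon given volume and its rate of change.

    F_out = F0 [ (Vv/Vv0)^(1/alpha) + tau_v/Vv0 (Vv/Vv0)^(-1/2) dVv/dt ].
    When coupled to dVv/dt = F_in - F_out the pair is solved algebraically;
    see :func:`resolve_balloon`.
    """
    vv = np.asarray(vv, dtype=float)
    if np.any(vv <= 0.0):
        raise ModelDomainError("venous volume must be positive")
    v = vv / params.vv_0
    out = params.f_0 * (
        v ** (1.0 / params.alpha_v)
        + params.tau_v / params.vv_0 * v ** (-0.5) * np.asarray(dvv_dt, float)
    )
    return float(out) if out.ndim == 0 else out


def resolve_balloon(vv, f_in, params: ParameterSet):
    """Solve the implicit balloon pair for F_out (and hence dVv/dt).

    Substituting dVv/dt = F_in - F_out into the outflow law gives a linear
    equation in F_out; returns (F_out, dVv/dt).
    """
    vv = np.asarray(vv, dtype=float)
    if np.any(vv <= 0.0):
        raise ModelDomainError("venous volume must be positive")
    v = vv / params.vv_0
    a = params.f_0 * params.tau_v / params.vv_0 * v ** (-0.5)
    f_out = (params.f_0 * v ** (1.0 / params.alpha_v) + a * np.asarray(f_in, float)) / (
        1.0 + a
    )
    dvv = np.asarray(f_in, float) - f_out
    if vv.ndim == 0 and np.ndim(f_out) == 0:
        return float(f_out), float(dvv)
    return f_out, dvv


# ----------------------------------------------------------------------
# full flux vector
# ----------------------------------------------------------------------
def _as_mapping(state) -> Mapping:
    """Accept a state vector (1-D or (n_t, 33) array) or a name->value mapping."""
    if isinstance(state, Mapping):
        return state
    y = np.asarray(state, dtype=float)
    if y.ndim == 1:
        return {n: y[i] for n, i in STATE_INDEX.items()}
    if y.ndim == 2 and y.shape[1] == len(STATE_INDEX):
        return {n: y[:, i] for n, i in STATE_INDEX.items()}
    raise ModelDomainError(f"cannot interpret state with shape {y.shape}")


def evaluate_fluxes(
    state,
    params: ParameterSet,
    f_exc=0.0,
    f_in=None,
    g_bar_total=0.0,
) -> dict:
    """Evaluate every reaction, transport, current and drive at a state.

    Parameters
    ----------
    state : array or mapping
        One state vector, or an (n_t, 33) stack of them.
    f_exc : scalar or array
        Presynaptic population rate (Hz).
    f_in : scalar or array, optional
        Blood inflow (s^-1); defaults to the baseline flow.
    g_bar_total : scalar
        ``N_exc * g_bar`` of the stimulus (mS cm^-2 s); together with
        ``f_exc`` it sets the excitatory conductance.

    Returns a dict keyed by flux name (units: mM s^-1 for fluxes, mV*mS*cm^-2
    for currents, s^-1 for flows).
    """
    s = _as_mapping(state)
    if f_in is None:
        f_in = params.f_0
    aden_n = adenylate_closure(s["ATP_n"], params)
    aden_g = adenylate_closure(s["ATP_g"], params)
    out: dict = {}
    for comp, x, aden in (("neuron", "n", aden_n), ("astrocyte", "g", aden_g)):
        psi_x = s["psi_n"] if x == "n" else params.psi_g
        pl = pump_and_leak(s[f"Na_{x}"], s[f"ATP_{x}"], psi_x, params, comp)
        out[f"J_pump_{x}"] = pl["J_pump"]
        out[f"J_leak_Na_{x}"] = pl["J_leak_Na"]
        gly = glycolysis_fluxes(s, aden, params, comp)
        out[f"J_HKPFK_{x}"] = gly["J_HKPFK"]
        out[f"J_PGK_{x}"] = gly["J_PGK"]
        out[f"J_PK_{x}"] = gly["J_PK"]
        out[f"J_LDH_{x}"] = ldh_flux(
            s[f"PYR_{x}"], s[f"NADH_cyto_{x}"], s[f"LAC_{x}"], params, comp
        )
        mito = mito_fluxes(s, aden, params, comp)
        out[f"J_mito_in_{x}"] = mito["J_mito_in"]
        out[f"J_mito_out_{x}"] = mito["J_mito_out"]
        out[f"J_shuttle_{x}"] = nadh_shuttle_flux(
            s[f"NADH_cyto_{x}"], s[f"NADH_mito_{x}"], params, comp
        )
        out[f"J_CK_{x}"] = creatine_kinase_flux(
            aden.adp, s[f"ATP_{x}"], s[f"PCr_{x}"], params, comp
        )
        out[f"J_O2mc_{x}"] = oxygen_exchange_flux(s[f"O2_{x}"], s["O2_c"], params, comp)
    # carriers
    out["J_GLC_en"] = carrier_flux(s["GLC_e"], s["GLC_n"], params.tmax_glc_en, params.kt_glc_en)
    out["J_GLC_eg"] = carrier_flux(s["GLC_e"], s["GLC_g"], params.tmax_glc_eg, params.kt_glc_eg)
    out["J_GLC_cg"] = carrier_flux(s["GLC_c"], s["GLC_g"], params.tmax_glc_cg, params.kt_glc_cg)
    out["J_GLC_ce"] = carrier_flux(s["GLC_c"], s["GLC_e"], params.tmax_glc_ce, params.kt_glc_ce)
    out["J_LAC_ne"] = carrier_flux(s["LAC_n"], s["LAC_e"], params.tmax_lac_ne, params.kt_lac_ne)
    out["J_LAC_ge"] = carrier_flux(s["LAC_g"], s["LAC_e"], params.tmax_lac_ge, params.kt_lac_ge)
    out["J_LAC_gc"] = carrier_flux(s["LAC_g"], s["LAC_c"], params.tmax_lac_gc, params.kt_lac_gc)
    out["J_LAC_ec"] = carrier_flux(s["LAC_e"], s["LAC_c"], params.tmax_lac_ec, params.kt_lac_ec)
    # capillary advection, balloon
    out.update(capillary_flows(s, f_in, params))
    f_out, dvv = resolve_balloon(s["Vv"], f_in, params)
    out["F_in"] = f_in
    out["F_out"] = f_out
    # membrane currents and drives
    out.update(hh_currents(s, aden_n, params))
    g_exc = np.asarray(g_bar_total, float) * np.asarray(f_exc, float)
    out["g_exc"] = g_exc
    out["I_syn"] = g_exc * (0.0 - s["psi_n"])  # E_AMPA = 0 mV, inward-positive
    return out
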