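"""Model parameters for the neuron-glia-vasculature (NGV) energy-metabolism model.

Every constant of the model is collected in :class:`ParameterSet`, grouped the
way the model's calibration treats them:

* ``fixed`` -- physical constants, volume fractions, channel conductances and
  transport affinities taken from the literature;
* ``optimized`` -- kinetic constants fitted against activity-evoked NADH
  transients measured in acute slices;
* ``constrained`` -- rate capacities solved algebraically so that the resting
  metabolite concentrations are a fixed point of the system (see
  :mod:`ngvsim.calibration`).

Units follow the model conventions throughout: concentrations in mM, time in
s, voltages in mV, conductances in mS cm^-2, fluxes in mM s^-1 (per the volume
of the compartment each equation is written for) and flows in s^-1.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

from .errors import ConfigError

__all__ = ["ParameterSet", "PARAM_GROUPS", "default_parameters"]


@dataclass
class ParameterSet:
    """All constants of the NGV model with their published default values.

    Attribute names mirror the field vocabulary: ``_n``/``_g`` suffixes denote
    the neuronal and astrocytic (glial) compartments, ``_e`` the extracellular
    space and ``_c`` the capillary; two-letter suffixes such as ``en`` label
    transport between two compartments (extracellular -> neuron).
    """

    # --- volume fractions and geometry (dimensionless, cm^-1) ---
    v_e: float = 0.2          #: extracellular volume fraction
    v_cap: float = 0.0055     #: capillary volume fraction
    v_g: float = 0.25         #: astrocytic volume fraction
    v_n: float = 0.45         #: neuronal volume fraction
    xi: float = 0.07          #: mitochondrial fraction of cell volume
    sm_vn: float = 2.5e4      #: neuronal surface-to-volume ratio (cm^-1)
    sm_vg: float = 2.5e4      #: astrocytic surface-to-volume ratio (cm^-1)

    # --- physical constants ---
    faraday: float = 9.64853e4  #: Faraday constant (C mol^-1)
    rt_f: float = 26.73         #: thermal voltage RT/F (mV)
    psi_g: float = -70.0        #: astrocytic membrane voltage, held fixed (mV)
    na_e: float = 150.0         #: extracellular sodium (mM)

    # --- carrier affinities (mM) ---
    kt_glc_en: float = 8.0
    kt_glc_eg: float = 8.0
    kt_glc_cg: float = 8.0
    kt_glc_ce: float = 8.0
    kt_lac_ne: float = 0.74
    kt_lac_ge: float = 3.5
    kt_lac_gc: float = 1.0
    kt_lac_ec: float = 1.0

    # --- hexokinase-phosphofructokinase (lumped) ---
    k_i_atp: float = 1.0      #: ATP inhibition constant (mM)
    n_h: float = 4.0          #: ATP inhibition Hill exponent
    k_g: float = 0.05         #: glucose affinity (mM)

    # --- oxygen carriage and exchange ---
    k_o2: float = 0.0361      #: plasma O2 at half Hb saturation (mM)
    hb_op: float = 8.6        #: hemoglobin O2-carrying capacity (mM)
    n_hb: float = 2.73        #: Hill exponent of Hb saturation
    k_o2_mito: float = 0.001  #: mitochondrial O2 affinity (mM)

    # --- Hodgkin-Huxley membrane ---
    c_m: float = 1e-3         #: membrane capacitance (mF cm^-2)
    g_l: float = 0.02         #: leak conductance (mS cm^-2)
    g_na: float = 40.0        #: transient sodium conductance (mS cm^-2)
    g_k: float = 18.0         #: delayed-rectifier conductance (mS cm^-2)
    g_ca: float = 0.02        #: high-threshold calcium conductance (mS cm^-2)
    g_mahp: float = 6.5       #: Ca-gated potassium (mAHP) conductance (mS cm^-2)
    k_d: float = 0.03         #: mAHP calcium affinity (mM)
    tau_ca: float = 0.15      #: calcium clearance time constant (s)
    ca_0: float = 0.5e-4      #: resting calcium (mM)
    e_k: float = -80.0        #: potassium reversal (mV)
    e_ca: float = 120.0       #: calcium reversal (mV)
    phi_n: float = 4.0        #: n-gate temperature factor
    phi_h: float = 4.0        #: h-gate temperature factor

    # --- venous balloon and arterial supply ---
    tau_v: float = 35.0       #: balloon viscoelastic time constant (s)
    alpha_v: float = 0.5      #: Grubb flow-volume exponent
    f_0: float = 0.012        #: baseline blood flow (s^-1)
    vv_0: float = 0.02        #: baseline venous volume fraction
    o2_a: float = 8.35        #: arterial oxygen (mM)
    glc_a: float = 4.75       #: arterial glucose (mM)

    # --- Na,K-ATPase and sodium leak ---
    g_na_n: float = 0.0136    #: neuronal sodium leak conductance (mS cm^-2)
    g_na_g: float = 0.0061    #: astrocytic sodium leak conductance (mS cm^-2)
    g_k_pas: float = 0.2035   #: passive potassium conductance, enters E_L (mS cm^-2)
    k_pump_n: float = 2.2e-6  #: neuronal pump rate (cm mM^-1 s^-1)
    k_pump_g: float = 4.5e-7  #: astrocytic pump rate (cm mM^-1 s^-1)
    j_pump0_g: float = 0.0687  #: baseline astrocytic pump flux (mM s^-1)
    k_m_pump: float = 0.5     #: pump ATP affinity (mM)
    na_0_n: float = 8.0       #: reference neuronal sodium in the pump current (mM)

    # --- conserved pools ---
    c_tot: float = 10.0       #: total creatine + phosphocreatine (mM)
    n_tot: float = 0.212      #: total NAD(H) per sub-compartment (mM)
    a_tot: float = 2.212      #: total adenine nucleotides (mM)
    q_ak: float = 0.92        #: adenylate kinase equilibrium constant

    # --- TCA cycle ---
    k_m_mito: float = 0.04    #: pyruvate affinity of the TCA step (mM)

    # --- BOLD weights ---
    k1: float = 2.22
    k2: float = 0.46
    k3: float = 0.43

    # === optimized parameters (fitted to NADH transients) ===
    kp_ldh_n: float = 72.3    #: LDH forward rate, neuron (mM^-1 s^-1)
    kp_ldh_g: float = 1.59    #: LDH forward rate, astrocyte (mM^-1 s^-1)
    m_cyto_n: float = 4.9e-8  #: shuttle cytosolic redox-ratio affinity, neuron
    m_cyto_g: float = 2.5e-4
    m_mito_n: float = 3.93e5  #: shuttle mitochondrial redox-ratio affinity, neuron
    m_mito_g: float = 1.06e4
    k_m_adp_n: float = 3.41e-3   #: ETC ADP affinity (mM)
    k_m_adp_g: float = 0.483e-3
    k_m_nadh_n: float = 4.44e-2  #: ETC NADH affinity (mM)
    k_m_nadh_g: float = 2.69e-2
    kp_ck_n: float = 0.0433   #: creatine kinase forward rate (mM^-1 s^-1)
    kp_ck_g: float = 0.00135
    k_m_nad_n: float = 0.409  #: TCA NAD+ affinity (mM)
    k_m_nad_g: float = 40.3

    # === constrained parameters (solved from resting-state balance) ===
    tmax_glc_en: float = 0.041    #: glucose carrier capacities (mM s^-1)
    tmax_glc_ce: float = 0.239
    tmax_glc_eg: float = 0.147
    tmax_glc_cg: float = 0.0016
    tmax_lac_gc: float = 0.00243  #: lactate carrier capacities (mM s^-1)
    tmax_lac_ne: float = 24.3
    tmax_lac_ge: float = 106.1
    tmax_lac_ec: float = 0.25
    k_hkpfk_n: float = 0.0504     #: HK-PFK rate (s^-1)
    k_hkpfk_g: float = 0.185
    km_ldh_n: float = 0.72        #: LDH reverse rate (mM^-1 s^-1)
    km_ldh_g: float = 0.071
    ps_cap_vn: float = 1.66       #: capillary-cell O2 conductance (s^-1)
    ps_cap_vg: float = 0.87
    vmax_out_n: float = 0.164     #: ETC capacity (mM s^-1)
    vmax_out_g: float = 0.064
    vmax_in_n: float = 0.1303     #: TCA capacity (mM s^-1)
    vmax_in_g: float = 5.7
    k_pgk_n: float = 3.97         #: phosphoglycerate kinase rate (mM^-1 s^-1)
    k_pgk_g: float = 135.2
    k_pk_n: float = 36.7          #: pyruvate kinase rate (mM^-1 s^-1)
    k_pk_g: float = 401.7
    j_atpases_n: float = 0.1695   #: housekeeping ATPase load (mM s^-1)
    j_atpases_g: float = 0.1404
    km_ck_n: float = 0.00028      #: creatine kinase reverse rate (mM^-1 s^-1)
    km_ck_g: float = 1e-5
    t_nadh_n: float = 10330.0     #: NADH shuttle capacity (mM s^-1)
    t_nadh_g: float = 150.0
    lac_a: float = 0.506          #: arterial lactate (mM)

    # ------------------------------------------------------------------
    # derived volume ratios
    # ------------------------------------------------------------------
    @property
    def r_en(self) -> float:
        return self.v_e / self.v_n

    @property
    def r_eg(self) -> float:
        return self.v_e / self.v_g

    @property
    def r_ce(self) -> float:
        return self.v_cap / self.v_e

    @property
    def r_cg(self) -> float:
        return self.v_cap / self.v_g

    @property
    def r_cn(self) -> float:
        return self.v_cap / self.v_n

    # ------------------------------------------------------------------
    # validation / bookkeeping
    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check strict positivity of capacities, affinities and volumes."""
        non_positive = [
            f.name
            for f in fields(self)
            if f.name in _POSITIVE and getattr(self, f.name) <= 0.0
        ]
        if non_positive:
            raise ConfigError(
                f"parameters must be strictly positive: {', '.join(non_positive)}"
            )

    def group(self, name: str) -> str:
        """Return the calibration group of a parameter: fixed / optimized / constrained."""
        try:
            return PARAM_GROUPS[name]
        except KeyError:
            raise ConfigError(f"unknown parameter {name!r}") from None

    def names(self, group: str | None = None) -> list[str]:
        if group is None:
            return [f.name for f in fields(self)]
        if group not in ("fixed", "optimized", "constrained"):
            raise ConfigError(f"unknown parameter group {group!r}")
        return [n for n, g in PARAM_GROUPS.items() if g == group]

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced (unknown keys rejected)."""
        _check_keys(overrides, PARAM_GROUPS, what="parameter")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def digest(self) -> str:
        """Stable content hash of the parameter values."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())

    # ------------------------------------------------------------------
    # serialization: flat YAML/JSON document with group tags
    # ------------------------------------------------------------------
    def to_document(self) -> dict[str, Any]:
        return {
            "values": self.as_dict(),
            "groups": dict(PARAM_GROUPS),
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_document()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=True))
        else:
            path.write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParameterSet":
        _check_keys(values, PARAM_GROUPS, what="parameter")
        return cls(**{k: float(v) for k, v in values.items()})

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ConfigError(f"parameter file {path} does not contain a mapping")
        values = doc.get("values", doc)
        if "groups" in doc:
            for name, grp in doc["groups"].items():
                if PARAM_GROUPS.get(name) != grp:
                    raise ConfigError(
                        f"parameter {name!r} tagged {grp!r}, expected "
                        f"{PARAM_GROUPS.get(name)!r}"
                    )
        return cls.from_dict(values)


def _check_keys(
    given: Mapping[str, Any], known: Mapping[str, Any], what: str
) -> None:
    for key in given:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown {what} {key!r}{suffix}")


def default_parameters() -> ParameterSet:
    """The published parameter set (calibration result, after rounding)."""
    return ParameterSet()


_FIXED = [
    "v_e", "v_cap", "v_g", "v_n", "xi", "sm_vn", "sm_vg",
    "faraday", "rt_f", "psi_g", "na_e",
    "kt_glc_en", "kt_glc_eg", "kt_glc_cg", "kt_glc_ce",
    "kt_lac_ne", "kt_lac_ge", "kt_lac_gc", "kt_lac_ec",
    "k_i_atp", "n_h", "k_g", "k_o2", "hb_op", "n_hb", "k_o2_mito",
    "c_m", "g_l", "g_na", "g_k", "g_ca", "g_mahp", "k_d", "tau_ca", "ca_0",
    "e_k", "e_ca", "phi_n", "phi_h",
    "tau_v", "alpha_v", "f_0", "vv_0", "o2_a", "glc_a",
    "g_na_n", "g_na_g", "g_k_pas", "k_pump_n", "k_pump_g", "j_pump0_g",
    "k_m_pump", "na_0_n", "c_tot", "n_tot", "a_tot", "q_ak", "k_m_mito",
    "k1", "k2", "k3",
]
_OPTIMIZED = [
    "kp_ldh_n", "kp_ldh_g",
    "m_cyto_n", "m_cyto_g", "m_mito_n", "m_mito_g",
    "k_m_adp_n", "k_m_adp_g", "k_m_nadh_n", "k_m_nadh_g",
    "kp_ck_n", "kp_ck_g", "k_m_nad_n", "k_m_nad_g",
]
_CONSTRAINED = [
    "tmax_glc_en", "tmax_glc_ce", "tmax_glc_eg", "tmax_glc_cg",
    "tmax_lac_gc", "tmax_lac_ne", "tmax_lac_ge", "tmax_lac_ec",
    "k_hkpfk_n", "k_hkpfk_g", "km_ldh_n", "km_ldh_g",
    "ps_cap_vn", "ps_cap_vg", "vmax_out_n", "vmax_out_g",
    "vmax_in_n", "vmax_in_g", "k_pgk_n", "k_pgk_g", "k_pk_n", "k_pk_g",
    "j_atpases_n", "j_atpases_g", "km_ck_n", "km_ck_g",
    "t_nadh_n", "t_nadh_g", "lac_a",
]

#: calibration group of every parameter
PARAM_GROUPS: dict[str, str] = (
    {n: "fixed" for n in _FIXED}
    | {n: "optimized" for n in _OPTIMIZED}
    | {n: "constrained" for n in _CONSTRAINED}
)

# parameters that may legitimately be negative or zero
_SIGNED = {"psi_g", "e_k", "e_ca"}
_POSITIVE = {n for n in PARAM_GROUPS} - _SIGNED
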