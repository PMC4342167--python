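"""Derived read-outs: BOLD, tissue mixtures, metabolic rates, transports.

All "relative" series are percent deviations from the run's own baseline
(the resting state the trajectory started from), matching how the
corresponding experiments are reported: NADH fluorescence and tissue
oxygen/lactate as relative fluctuations, metabolic rates as percent increases
over rest.

Tissue mixtures are volume-weighted means.  The NADH tissue signal weights
the four sub-pools by cell volume times the cytosolic (1-xi) or mitochondrial
(xi) sub-volume; tissue lactate mixes neurons, astrocytes, extracellular
space and capillary by their volume fractions; intra-parenchymal oxygen is
the cell-volume-weighted mean of neuronal and astrocytic oxygen (the model
has no extracellular oxygen pool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Trajectory
from .errors import ModelDomainError
from .state import STATE_INDEX

__all__ = [
    "ObservableSeries",
    "bold_signal",
    "tissue_mix",
    "nadh_transients",
    "metabolic_rates",
    "lactate_transports",
    "firing_rate",
    "scenario_summary",
]


@dataclass
class ObservableSeries:
    """One named read-out on the trajectory's time grid."""

    name: str
    t: np.ndarray
    values: np.ndarray
    baseline: float
    units: str = "%"
    mask: np.ndarray | None = None  #: True where the value is undefined

    def min(self) -> float:
        return float(np.min(self.values))

    def max(self) -> float:
        return float(np.max(self.values))

    def window(self, t_lo: float, t_hi: float) -> np.ndarray:
        sel = (self.t >= t_lo) & (self.t <= t_hi)
        return self.values[sel]


def _relative(name: str, t, absolute: np.ndarray, baseline: float) -> ObservableSeries:
    return ObservableSeries(
        name=name,
        t=np.asarray(t),
        values=100.0 * (np.asarray(absolute) / baseline - 1.0),
        baseline=baseline,
        units="%",
    )


# ----------------------------------------------------------------------
def bold_signal(traj: Trajectory) -> ObservableSeries:
    """Forward BOLD signal (%) from deoxyhemoglobin and venous volume.

    ``BOLD = Vv0 [ (k1+k2)(1 - dHb/dHb0) - (k2+k3)(1 - Vv/Vv0) ]`` with the
    baselines taken from the run's own resting state; exactly zero at rest.
    """
    p = traj.params
    dhb0 = float(traj.baseline[STATE_INDEX["dHb"]])
    vv0 = float(traj.baseline[STATE_INDEX["Vv"]])
    dhb = traj.state("dHb")
    vv = traj.state("Vv")
    bold = vv0 * (
        (p.k1 + p.k2) * (1.0 - dhb / dhb0) - (p.k2 + p.k3) * (1.0 - vv / vv0)
    )
    return ObservableSeries("BOLD", traj.t, 100.0 * bold, baseline=0.0, units="%")


def tissue_mix(traj: Trajectory, quantity: str) -> ObservableSeries:
    """Volume-weighted tissue mixture of NADH, lactate or oxygen (relative, %)."""
    p = traj.params
    if quantity == "NADH":
        comps = ["NADH_cyto_n", "NADH_mito_n", "NADH_cyto_g", "NADH_mito_g"]
        weights = [
            (1.0 - p.xi) * p.v_n, p.xi * p.v_n,
            (1.0 - p.xi) * p.v_g, p.xi * p.v_g,
        ]
    elif quantity == "LAC":
        comps = ["LAC_n", "LAC_g", "LAC_e", "LAC_c"]
        weights = [p.v_n, p.v_g, p.v_e, p.v_cap]
    elif quantity == "O2":
        comps = ["O2_n", "O2_g"]
        weights = [p.v_n, p.v_g]
    else:
        raise ModelDomainError(f"no tissue mixture defined for {quantity!r}")
    w = np.asarray(weights) / np.sum(weights)
    mix = sum(wi * traj.state(c) for wi, c in zip(w, comps))
    base = float(sum(wi * traj.baseline[STATE_INDEX[c]] for wi, c in zip(w, comps)))
    return _relative(f"tissue_{quantity}", traj.t, mix, base)


def nadh_transients(traj: Trajectory) -> dict[str, ObservableSeries]:
    """Relative NADH in the compartments reported by slice fluorescence.

    Returns the neuronal mitochondrial, astrocytic cytosolic and whole-tissue
    series (percent deviation from rest).
    """
    out = {}
    for key, state in (("neuron_mito", "NADH_mito_n"), ("astro_cyto", "NADH_cyto_g")):
        base = float(traj.baseline[STATE_INDEX[state]])
        out[key] = _relative(key, traj.t, traj.state(state), base)
    out["tissue"] = tissue_mix(traj, "NADH")
    return out


def metabolic_rates(traj: Trajectory) -> dict[str, ObservableSeries]:
    """CMRglc, CMRO2 (mM/s per tissue volume), their cell-type splits and OGI.

    Glucose consumption is measured at the committed HK-PFK step (membrane
    transport is reversible in this model); oxygen consumption is 0.6 times
    the electron-transport flux.  OGI = CMRO2 / CMRglc, flagged undefined
    where CMRglc vanishes.
    """
    p = traj.params
    fl = traj.fluxes()
    glc_n = p.v_n * fl["J_HKPFK_n"].to_numpy()
    glc_g = p.v_g * fl["J_HKPFK_g"].to_numpy()
    o2_n = 0.6 * p.v_n * fl["J_mito_out_n"].to_numpy()
    o2_g = 0.6 * p.v_g * fl["J_mito_out_g"].to_numpy()
    cmrglc = glc_n + glc_g
    cmro2 = o2_n + o2_g
    t = traj.t
    undefined = np.abs(cmrglc) < 1e-15
    with np.errstate(divide="ignore", invalid="ignore"):
        ogi = np.where(undefined, np.nan, cmro2 / np.where(undefined, 1.0, cmrglc))
    mk = lambda name, v: ObservableSeries(name, t, v, baseline=float(v[0]), units="mM/s")
    out = {
        "CMRglc": mk("CMRglc", cmrglc),
        "CMRglc_n": mk("CMRglc_n", glc_n),
        "CMRglc_g": mk("CMRglc_g", glc_g),
        "CMRO2": mk("CMRO2", cmro2),
        "CMRO2_n": mk("CMRO2_n", o2_n),
        "CMRO2_g": mk("CMRO2_g", o2_g),
        "OGI": ObservableSeries("OGI", t, ogi, baseline=float(ogi[0]), units="1",
                                mask=undefined),
    }
    return out


def lactate_transports(traj: Trajectory) -> dict[str, ObservableSeries]:
    """Net lactate transports and LDH activities with the reporting convention.

    ``J_LAC_ab`` is positive for net a -> b transfer, so a neuron importing
    lactate from the extracellular space shows a negative ``J_LAC_ne``; a
    neuronal LDH running lactate -> pyruvate shows a negative ``J_LDH_n``.
    """
    fl = traj.fluxes()
    t = traj.t
    names = ["J_LAC_ge", "J_LAC_ne", "J_LAC_ec", "J_LAC_gc", "J_LDH_n", "J_LDH_g"]
    return {
        n: ObservableSeries(n, t, fl[n].to_numpy(), baseline=float(fl[n].iloc[0]),
                            units="mM/s")
        for n in names
    }


def firing_rate(traj: Trajectory) -> ObservableSeries:
    """Instantaneous firing rate: inverse inter-spike interval at ISI midpoints.

    Empty when fewer than two spikes were detected.
    """
    s = np.asarray(traj.spike_times, dtype=float)
    if s.size < 2:
        return ObservableSeries("firing_rate", np.empty(0), np.empty(0), 0.0, "Hz")
    isi = np.diff(s)
    mid = 0.5 * (s[1:] + s[:-1])
    return ObservableSeries("firing_rate", mid, 1.0 / isi, baseline=0.0, units="Hz")


# ----------------------------------------------------------------------
# per-scenario summary metrics
# ----------------------------------------------------------------------
def _half_rise_time(series: ObservableSeries) -> float:
    """First time the series reaches half of its eventual maximum."""
    peak = series.max()
    if peak <= 0.0:
        return float("nan")
    above = series.values >= 0.5 * peak
    return float(series.t[np.argmax(above)]) if above.any() else float("nan")


def _is_monophasic(series: ObservableSeries, tol_pp: float = 0.5) -> bool:
    """Single-signed response: never deflects the other way by more than tol."""
    return bool(series.min() > -tol_pp)


def scenario_summary(traj: Trajectory) -> dict:
    """Headline metrics of a run, keyed by what the experiments report.

    The metric set depends on the scenario kind; every value is computed from
    the trajectory (no stored constants).
    """
    kind = traj.scenario.kind
    t_end = traj.scenario.stimulus.t_end
    out: dict = {
        "kind": kind,
        "n_spikes": int(traj.spike_times.size),
        "last_spike_s": float(traj.spike_times.max()) if traj.spike_times.size else None,
    }
    nadh = nadh_transients(traj)
    neuron = nadh["neuron_mito"]
    astro = nadh["astro_cyto"]
    i_dip = int(np.argmin(neuron.values))
    out["nadh_neuron_mito_dip_pct"] = float(neuron.values[i_dip])
    out["nadh_neuron_mito_dip_time_s"] = float(neuron.t[i_dip])
    out["nadh_neuron_mito_overshoot_pct"] = float(
        np.max(neuron.values[traj.t > t_end]) if np.any(traj.t > t_end) else np.nan
    )
    out["nadh_astro_cyto_peak_pct"] = astro.max()
    out["nadh_astro_half_rise_s"] = _half_rise_time(astro)
    out["nadh_astro_monophasic"] = _is_monophasic(astro)
    lac = tissue_mix(traj, "LAC")
    lac_e = _relative("LAC_e", traj.t, traj.state("LAC_e"),
                      float(traj.baseline[STATE_INDEX["LAC_e"]]))
    out["lactate_tissue_vs_extracellular_max_diff_pp"] = float(
        np.max(np.abs(lac.values - lac_e.values))
    )
    out["lactate_tissue_peak_pct"] = lac.max()

    if kind in ("in_vivo_rodent", "in_vivo_human"):
        o2 = tissue_mix(traj, "O2")
        out["o2_dip_pct"] = float(np.min(o2.window(0.0, 5.0)))
        out["o2_overshoot_pct"] = float(np.max(o2.window(0.0, t_end)))
        out["o2_plateau_pct"] = float(np.mean(o2.window(t_end - 20.0, t_end)))
        out["o2_undershoot_pct"] = float(np.min(o2.window(t_end, traj.t[-1])))
        trans = lactate_transports(traj)
        jec = trans["J_LAC_ec"]
        base = jec.baseline
        post_peak = float(np.max(jec.window(t_end, traj.t[-1])))
        out["lac_export_ec_baseline"] = base
        out["lac_export_ec_post_peak"] = post_peak
        out["lac_export_ec_increase_pct"] = 100.0 * (post_peak / base - 1.0)

    if kind == "in_vivo_human":
        rates = metabolic_rates(traj)
        sel_late = (traj.t >= t_end - 100.0) & (traj.t <= t_end)
        for key in ("CMRglc", "CMRO2"):
            series = rates[key]
            plateau = float(np.mean(series.values[sel_late]))
            out[f"{key.lower()}_increase_pct"] = 100.0 * (plateau / series.baseline - 1.0)
        out["cmrglc_neuron_share_plateau"] = float(
            np.mean(rates["CMRglc_n"].values[sel_late])
            / np.mean(rates["CMRglc"].values[sel_late])
        )
        out["cmro2_neuron_share_plateau"] = float(
            np.mean(rates["CMRO2_n"].values[sel_late])
            / np.mean(rates["CMRO2"].values[sel_late])
        )
        ogi = rates["OGI"]
        out["ogi_baseline"] = ogi.baseline
        out["ogi_plateau"] = float(np.nanmean(ogi.values[sel_late]))
        out["lactate_dip_pct"] = float(np.min(lac.window(0.0, 60.0)))
        out["lactate_plateau_pct"] = float(np.mean(lac.window(t_end - 100.0, t_end)))
        bold = bold_signal(traj)
        out["bold_onset_dip_pct"] = float(np.min(bold.window(0.0, 5.0)))
        out["bold_peak_pct"] = bold.max()
    return out
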