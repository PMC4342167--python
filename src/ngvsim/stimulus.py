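"""External drives and experiment scenarios.

The model is driven by two independent inputs:

* a presynaptic glutamatergic population of ``n_exc`` neurons whose rate
  decays exponentially from ``f_0`` to ``f_inf`` during the stimulation
  window.  It generates an excitatory AMPA conductance on the neuron (hence a
  synaptic current and sodium entry) and a sodium co-transport drive on the
  astrocyte through glutamate uptake (3 Na+ per glutamate);
* the cerebral blood flow, either held at baseline (slice conditions) or
  following a delayed double-exponential functional-hyperemia curve that
  peaks early and relaxes to a 10 % plateau.

Three stock scenarios mirror the experimental settings the model is compared
against: a 20 s slice stimulation with clamped capillary/vascular states
(``in_vitro``), a 60 s rodent stimulation (``in_vivo_rodent``) and a 900 s
human imaging block (``in_vivo_human``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ConfigError
from .state import CAPILLARY_VASCULAR_STATES, STATE_INDEX

__all__ = [
    "StimulusSpec",
    "FlowSpec",
    "ScenarioSpec",
    "excitatory_rate",
    "synaptic_drive",
    "astrocytic_drive",
    "cbf",
    "make_scenario",
    "SCENARIO_KINDS",
]

SCENARIO_KINDS = ("in_vitro", "in_vivo_rodent", "in_vivo_human")


@dataclass(frozen=True)
class StimulusSpec:
    """Presynaptic drive: population size, unitary conductance and rate decay."""

    n_exc: float = 1500.0     #: presynaptic population size
    g_bar: float = 7.8e-6     #: conductance surface per event (mS cm^-2 s)
    f_0: float = 3.2          #: initial population rate (Hz)
    f_inf: float = 0.5        #: late sustained rate (Hz)
    tau_f: float = 2.5        #: rate decay time constant (s)
    delta_glut: float = 2.25e-5  #: glutamate released per presynaptic spike (mM)
    e_ampa: float = 0.0       #: AMPA reversal potential (mV)
    t_0: float = 0.0          #: stimulation onset (s)
    t_end: float = 20.0       #: stimulation offset (s)

    def __post_init__(self) -> None:
        if not (self.f_0 >= self.f_inf >= 0.0):
            raise ConfigError("stimulus rates must satisfy f_0 >= f_inf >= 0")
        if self.tau_f <= 0.0:
            raise ConfigError("tau_f must be positive")
        if self.t_end <= self.t_0:
            raise ConfigError("t_end must exceed t_0")

    def rate(self, t: float) -> float:
        """Population rate at time ``t`` (zero outside the stimulation window)."""
        if t < self.t_0 or t > self.t_end:
            return 0.0
        return self.f_inf + (self.f_0 - self.f_inf) * math.exp(-(t - self.t_0) / self.tau_f)


@dataclass(frozen=True)
class FlowSpec:
    """Cerebral-blood-flow time course parameters."""

    f_0: float = 0.012        #: baseline flow (s^-1)
    t_1: float = 1.0          #: hemodynamic delay after stimulus onset (s)
    rise_tau: float = 5.0     #: slow exponential of the transient (s)
    fall_tau: float = 2.0     #: fast exponential of the transient (s)
    recovery_tau: float = 5.0  #: post-stimulus return to baseline (s)
    plateau: float = 1.1      #: sustained flow during stimulation (x baseline)
    peak_amp: float = 1.5     #: amplitude of the biexponential transient
    profile_kind: str = "rodent"  #: 'rodent', 'human' or 'constant'

    def __post_init__(self) -> None:
        if self.f_0 <= 0.0:
            raise ConfigError("baseline flow must be positive")
        if self.profile_kind not in ("rodent", "human", "constant"):
            raise ConfigError(f"unknown flow profile {self.profile_kind!r}")

    def __call__(self, t: float, t_end: float) -> float:
        return cbf(t, self, t_end)


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete experiment: stimulus, flow, clamping rules and duration."""

    kind: str
    stimulus: StimulusSpec
    flow: FlowSpec
    clamped_states: tuple[str, ...] = ()
    total_duration: float = 90.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        for name in self.clamped_states:
            if name not in STATE_INDEX:
                raise ConfigError(f"unknown clamped state {name!r}")
        if self.kind == "in_vitro":
            if set(self.clamped_states) != set(CAPILLARY_VASCULAR_STATES):
                raise ConfigError(
                    "the in vitro scenario clamps exactly the capillary/vascular states"
                )
        elif self.clamped_states:
            raise ConfigError("in vivo scenarios clamp no states")
        if self.total_duration < self.stimulus.t_end:
            raise ConfigError("total_duration must cover the stimulation window")

    def flow_function(self) -> Callable[[float], float] | None:
        """Time -> inflow map for the integrator (None = constant baseline)."""
        if self.flow.profile_kind == "constant":
            return None
        t_end = self.stimulus.t_end
        spec = self.flow
        return lambda t: cbf(t, spec, t_end)


def excitatory_rate(t, spec: StimulusSpec):
    """Presynaptic population rate (Hz); vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    inside = (t >= spec.t_0) & (t <= spec.t_end)
    val = spec.f_inf + (spec.f_0 - spec.f_inf) * np.exp(
        -np.clip(t - spec.t_0, 0.0, None) / spec.tau_f
    )
    out = np.where(inside, val, 0.0)
    return float(out) if out.ndim == 0 else out


def synaptic_drive(t, psi, i_na, spec: StimulusSpec, params) -> dict:
    """Excitatory conductance, synaptic current and neuronal sodium drive.

    ``I_syn = g_exc (E_AMPA - psi)`` is inward-positive: it depolarizes the
    neuron and, together with the (inward-negative) voltage-gated sodium
    current, raises intracellular sodium through
    ``J_stim_n = S_m V_n / F (2/3 I_syn - I_Na)``.
    """
    g_exc = spec.n_exc * spec.g_bar * excitatory_rate(t, spec)
    i_syn = g_exc * (spec.e_ampa - np.asarray(psi, float))
    j_stim = params.sm_vn / params.faraday * ((2.0 / 3.0) * i_syn - np.asarray(i_na, float))
    return {"g_exc": g_exc, "I_syn": i_syn, "Jstim_n": j_stim}


def astrocytic_drive(t, spec: StimulusSpec):
    """Astrocytic sodium drive from glutamate uptake (3 Na+ per glutamate), mM/s."""
    out = 3.0 * spec.delta_glut * spec.n_exc * excitatory_rate(t, spec)
    return float(out) if np.ndim(out) == 0 else out


def cbf(t, spec: FlowSpec, t_end: float):
    """Cerebral blood flow (s^-1) at time ``t`` for a stimulation ending at ``t_end``.

    Baseline before the hemodynamic delay ``t_1``; during stimulation a
    biexponential transient on top of the sustained plateau,
    ``F0 (plateau + amp [exp(-(t-t1)/rise) - exp(-(t-t1)/fall)])``; after the
    stimulation an exponential return to baseline, continuous at ``t_end``.
    """
    t = np.asarray(t, dtype=float)
    f0 = spec.f_0
    if spec.profile_kind == "constant":
        out = np.full_like(t, f0)
        return float(out) if out.ndim == 0 else out

    def during(tt):
        s = tt - spec.t_1
        return f0 * (
            spec.plateau
            + spec.peak_amp * (np.exp(-s / spec.rise_tau) - np.exp(-s / spec.fall_tau))
        )

    f_at_end = during(np.asarray(t_end)) if t_end >= spec.t_1 else f0
    out = np.where(
        t < spec.t_1,
        f0,
        np.where(
            t <= t_end,
            during(np.clip(t, spec.t_1, None)),
            f0 + (f_at_end - f0) * np.exp(-np.clip(t - t_end, 0.0, None) / spec.recovery_tau),
        ),
    )
    return float(out) if out.ndim == 0 else out


def make_scenario(kind: str, **overrides) -> ScenarioSpec:
    """Build one of the three stock scenarios.

    ``in_vitro``: 20 s stimulation, constant baseline flow, capillary and
    vascular states clamped at rest.  ``in_vivo_rodent``: 60 s stimulation
    with the delayed hyperemia curve.  ``in_vivo_human``: 900 s block with the
    same curve shape (no human-specific constants are published; override
    ``flow`` fields to change the plateau).

    Keyword overrides: ``stim_duration`` (s), ``total_duration`` (s),
    ``flow_delay`` (s), plus any :class:`StimulusSpec` / :class:`FlowSpec`
    field via the ``stimulus`` / ``flow`` dataclass-replacement dicts.
    """
    known = {"stim_duration", "total_duration", "flow_delay", "stimulus", "flow"}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown scenario overrides: {sorted(unknown)}")
    if kind == "in_vitro":
        stim_end, total = 20.0, 90.0
        flow = FlowSpec(profile_kind="constant")
        clamped = CAPILLARY_VASCULAR_STATES
    elif kind == "in_vivo_rodent":
        stim_end, total = 60.0, 240.0
        flow = FlowSpec(profile_kind="rodent")
        clamped = ()
    elif kind == "in_vivo_human":
        stim_end, total = 900.0, 1200.0
        flow = FlowSpec(profile_kind="human")
        clamped = ()
    else:
        raise ConfigError(f"unknown scenario kind {kind!r}")
    stim_end = float(overrides.get("stim_duration", stim_end))
    default_margin = total - (20.0 if kind == "in_vitro" else 60.0 if kind == "in_vivo_rodent" else 900.0)
    total = float(overrides.get("total_duration", stim_end + default_margin))
    stimulus = StimulusSpec(t_0=0.0, t_end=stim_end)
    if "stimulus" in overrides:
        stimulus = replace(stimulus, **overrides["stimulus"])
    if "flow_delay" in overrides:
        flow = replace(flow, t_1=float(overrides["flow_delay"]))
    if "flow" in overrides:
        flow = replace(flow, **overrides["flow"])
    return ScenarioSpec(
        kind=kind,
        stimulus=stimulus,
        flow=flow,
        clamped_states=clamped,
        total_duration=total,
    )
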