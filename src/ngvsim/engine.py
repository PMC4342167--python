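"""Stiff integration, steady states and trajectories.

The system couples millisecond membrane dynamics to metabolic and vascular
processes with time constants of tens of seconds, so it is integrated with an
adaptive stiff solver (LSODA) under a two-regime step policy: while the
stimulus is on and the membrane is firing, the maximum step is capped at
1e-4 s so every action potential is resolved; once a whole detection window
passes without a spike the cap is released and the solver strides over the
slow metabolic relaxation.  Spikes are located exactly by event detection
(upward crossing of the membrane voltage through 0 mV).

Steady states are found by a scaled Newton-type solve (MINPACK hybr) of the
reference right-hand side seeded from the published resting values, and their
local stability is assessed from the finite-difference Jacobian spectrum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._version import __version__ as _version
from . import fluxes as fx
from .errors import ConfigError, ModelDomainError, SolverError
from .params import ParameterSet
from .rhs import compute_derivatives, make_fast_rhs
from .state import N_STATES, STATE_INDEX, STATE_NAMES, resting_state
from .stimulus import ScenarioSpec, excitatory_rate

__all__ = [
    "Trajectory",
    "SteadyStateReport",
    "StabilityVerdict",
    "integrate",
    "find_steady_state",
    "stability_check",
]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class Trajectory:
    """A simulated time course: states, inputs and spike times on one grid."""

    t: np.ndarray                    #: sample times (s), strictly increasing
    states: np.ndarray               #: (n_t, 33) state matrix
    spike_times: np.ndarray          #: times of upward 0 mV crossings (s)
    scenario: ScenarioSpec
    params: ParameterSet
    rtol: float
    _fluxes: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0.0):
            raise ModelDomainError("trajectory time grid must be strictly increasing")

    # -- accessors ------------------------------------------------------
    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_INDEX[name]]

    @property
    def baseline(self) -> np.ndarray:
        """The initial (resting) state the run started from."""
        return self.states[0]

    @property
    def f_exc(self) -> np.ndarray:
        return excitatory_rate(self.t, self.scenario.stimulus)

    @property
    def f_in(self) -> np.ndarray:
        flow = self.scenario.flow_function()
        if flow is None:
            return np.full_like(self.t, self.params.f_0)
        return np.array([flow(tt) for tt in self.t])

    def fluxes(self) -> pd.DataFrame:
        """All reaction/transport/current traces, evaluated on the grid (cached)."""
        if self._fluxes is None:
            stim = self.scenario.stimulus
            raw = fx.evaluate_fluxes(
                self.states,
                self.params,
                f_exc=self.f_exc,
                f_in=self.f_in,
                g_bar_total=stim.n_exc * stim.g_bar,
            )
            cols = {
                k: (np.broadcast_to(v, self.t.shape) if np.ndim(v) == 0 else v)
                for k, v in raw.items()
            }
            j_stim_n = self.params.sm_vn / self.params.faraday * (
                (2.0 / 3.0) * cols["I_syn"] - cols["I_Na"]
            )
            cols["Jstim_n"] = j_stim_n
            cols["Jstim_g"] = 3.0 * stim.delta_glut * stim.n_exc * self.f_exc
            self._fluxes = pd.DataFrame(cols, index=self.t)
        return self._fluxes

    def to_frame(self, include_fluxes: bool = True) -> pd.DataFrame:
        """Tidy table: one row per sample, one column per state (and flux)."""
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_s", self.t)
        df["f_exc"] = self.f_exc
        df["F_in"] = self.f_in
        if include_fluxes:
            df = pd.concat([df, self.fluxes().reset_index(drop=True)], axis=1)
        return df

    # -- persistence ----------------------------------------------------
    def manifest(self, extra: Mapping | None = None) -> dict:
        doc = {
            "format": "ngvsim-trajectory-v1",
            "version": _version,
            "scenario": _scenario_doc(self.scenario),
            "params": self.params.as_dict(),
            "params_digest": self.params.digest(),
            "rtol": self.rtol,
            "spike_times": [float(s) for s in self.spike_times],
            "n_samples": int(self.t.size),
        }
        if extra:
            doc.update(extra)
        return doc

    def save(self, csv_path: str | Path, manifest_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        # %.17g round-trips IEEE doubles exactly
        self.to_frame(include_fluxes=True).to_csv(
            csv_path, index=False, float_format="%.17g"
        )
        if manifest_path is None:
            manifest_path = csv_path.with_suffix(".manifest.json")
        Path(manifest_path).write_text(json.dumps(self.manifest(), indent=1))

    @classmethod
    def load(cls, csv_path: str | Path, manifest_path: str | Path | None = None) -> "Trajectory":
        csv_path = Path(csv_path)
        if manifest_path is None:
            manifest_path = csv_path.with_suffix(".manifest.json")
            if not Path(manifest_path).exists():
                sibling = csv_path.parent / "manifest.json"
                if sibling.exists():
                    manifest_path = sibling
        if not Path(manifest_path).exists():
            raise ConfigError(f"no manifest found next to {csv_path}")
        doc = json.loads(Path(manifest_path).read_text())
        df = pd.read_csv(csv_path, float_precision="round_trip")
        scenario = _scenario_from_doc(doc["scenario"])
        params = ParameterSet.from_dict(doc["params"])
        return cls(
            t=df["time_s"].to_numpy(),
            states=df[list(STATE_NAMES)].to_numpy(),
            spike_times=np.asarray(doc["spike_times"], dtype=float),
            scenario=scenario,
            params=params,
            rtol=float(doc["rtol"]),
        )


def _scenario_doc(sc: ScenarioSpec) -> dict:
    return {
        "kind": sc.kind,
        "stimulus": dataclasses.asdict(sc.stimulus),
        "flow": dataclasses.asdict(sc.flow),
        "clamped_states": list(sc.clamped_states),
        "total_duration": sc.total_duration,
    }


def _scenario_from_doc(doc: Mapping) -> ScenarioSpec:
    from .stimulus import FlowSpec, StimulusSpec

    return ScenarioSpec(
        kind=doc["kind"],
        stimulus=StimulusSpec(**doc["stimulus"]),
        flow=FlowSpec(**doc["flow"]),
        clamped_states=tuple(doc["clamped_states"]),
        total_duration=float(doc["total_duration"]),
    )


@dataclass
class SteadyStateReport:
    """Result of a fixed-point solve with its local stability information."""

    state: np.ndarray
    residual_norm: float
    jacobian_eigenvalues: np.ndarray
    stable: bool
    converged: bool
    free_states: tuple[str, ...]

    def state_dict(self) -> dict[str, float]:
        return {n: float(self.state[i]) for n, i in STATE_INDEX.items()}


@dataclass(frozen=True)
class StabilityVerdict:
    stable: bool
    max_real_part: float
    eigenvalues: np.ndarray


# ----------------------------------------------------------------------
# integration
# ----------------------------------------------------------------------
def integrate(
    scenario: ScenarioSpec,
    params: ParameterSet | None = None,
    *,
    y0: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol_floor: float = 1e-12,
    atol_scale: float = 1e-8,
    max_step_spiking: float = 1e-4,
    spike_window: float = 5.0,
    dt_fine: float = 1e-3,
    dt_coarse: float = 0.1,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a scenario from its resting state and return the trajectory.

    Output is sampled every ``dt_fine`` while the spike-resolving step cap is
    active and every ``dt_coarse`` afterwards; spike times come from exact
    event detection and are not limited by the sampling.  Two calls with
    identical inputs produce identical output.
    """
    params = params or ParameterSet()
    if y0 is None:
        y0 = find_steady_state(params).state
    y0 = np.asarray(y0, dtype=float)
    stim = scenario.stimulus
    flow = scenario.flow_function()
    rhs = make_fast_rhs(params, stim, flow, clamp=scenario.clamped_states)
    atol = np.abs(y0) * atol_scale + atol_floor

    def spike(t, y):
        return y[STATE_INDEX["psi_n"]]

    spike.direction = 1.0

    total = float(scenario.total_duration)
    breakpoints = {0.0, total, float(stim.t_end)}
    if flow is not None:
        breakpoints.add(float(scenario.flow.t_1))
    breakpoints = sorted(b for b in breakpoints if 0.0 <= b <= total)

    t_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    spikes: list[float] = []
    t_cur, y_cur = 0.0, y0
    capped = True
    while t_cur < total - 1e-12:
        nxt_break = min(b for b in breakpoints if b > t_cur + 1e-12)
        t_next = min(t_cur + spike_window, nxt_break) if capped else nxt_break
        dt = dt_fine if capped else dt_coarse
        grid = np.arange(t_cur, t_next, dt)
        if grid.size == 0 or grid[-1] < t_next:
            grid = np.append(grid, t_next)
        sol = solve_ivp(
            rhs,
            (t_cur, t_next),
            y_cur,
            method=method,
            rtol=rtol,
            atol=atol,
            max_step=max_step_spiking if capped else np.inf,
            t_eval=grid,
            events=spike,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t_cur:.4g}: "
                f"{sol.message}",
                t=float(sol.t[-1]) if sol.t.size else t_cur,
                state=sol.y[:, -1] if sol.y.size else y_cur,
            )
        seg_spikes = [float(s) for s in sol.t_events[0]]
        spikes.extend(seg_spikes)
        # drop the duplicated segment start
        start = 1 if t_parts else 0
        t_parts.append(sol.t[start:])
        y_parts.append(sol.y[:, start:].T)
        y_cur = sol.y[:, -1]
        t_cur = t_next
        if capped and not seg_spikes and t_cur >= min(spike_window, stim.t_end):
            capped = False

    t = np.concatenate(t_parts)
    states = np.concatenate(y_parts, axis=0)
    if not np.all(np.isfinite(states)):
        raise SolverError("trajectory contains non-finite states")
    return Trajectory(
        t=t,
        states=states,
        spike_times=np.asarray(spikes, dtype=float),
        scenario=scenario,
        params=params,
        rtol=rtol,
    )


# ----------------------------------------------------------------------
# steady state and stability
# ----------------------------------------------------------------------
def _steady_rhs(params: ParameterSet, clamp: Iterable[str]) -> Callable:
    """Autonomous right-hand side (no stimulus, baseline flow) for root finding.

    Uses the unchecked fast path so that exploratory iterates slightly outside
    the physical domain do not abort the solve; genuinely singular points are
    mapped to a large residual that pushes the solver back.
    """
    from .stimulus import StimulusSpec

    off = StimulusSpec(f_0=0.0, f_inf=0.0, t_0=-2.0, t_end=-1.0)
    fast = make_fast_rhs(params, off, None, clamp=clamp)

    def fun(y: np.ndarray) -> np.ndarray:
        try:
            dy = fast(0.0, y)
        except (ValueError, ZeroDivisionError, OverflowError):
            return np.full(N_STATES, 1e6)
        if not np.all(np.isfinite(dy)):
            return np.full(N_STATES, 1e6)
        return dy

    return fun


def find_steady_state(
    params: ParameterSet | None = None,
    clamp_mask: Iterable[str] = (),
    *,
    seed: np.ndarray | None = None,
    tol: float = 1e-13,
    residual_tol: float = 1e-9,
) -> SteadyStateReport:
    """Solve for the resting fixed point of the (unclamped) subsystem.

    The solve is performed in units of the published resting values so that
    all 33 components are O(1); clamped states are held at their seed values.
    Raises :class:`SolverError` if the residual does not meet ``residual_tol``.
    """
    params = params or ParameterSet()
    seed = resting_state() if seed is None else np.asarray(seed, dtype=float)
    clamp = tuple(clamp_mask)
    clamped_ix = [STATE_INDEX[n] for n in clamp]
    free_ix = np.array([i for i in range(N_STATES) if i not in clamped_ix], dtype=int)
    free_names = tuple(STATE_NAMES[i] for i in free_ix)
    rhs_fun = _steady_rhs(params, clamp)
    scale = np.where(np.abs(seed) > 0, np.abs(seed), 1.0)

    def residual(z: np.ndarray) -> np.ndarray:
        y = seed.copy()
        y[free_ix] = z * scale[free_ix]
        return rhs_fun(y)[free_ix] / scale[free_ix]

    def solve_from(z0: np.ndarray):
        sol = root(residual, z0, method="hybr", tol=tol)
        y = seed.copy()
        y[free_ix] = sol.x * scale[free_ix]
        return sol, y, float(np.max(np.abs(rhs_fun(y)[free_ix])))

    sol, y_ss, res = solve_from(seed[free_ix] / scale[free_ix])
    if not sol.success or res > residual_tol:
        # relax onto the (stable) fixed point by pseudo-time integration,
        # then polish with Newton from the relaxed state; lengthen the
        # relaxation horizon until the slow pools (PCr, NADH) settle
        y_relax = seed
        for horizon in (4e4, 4e5, 4e6):
            relaxed = solve_ivp(
                lambda t, y: rhs_fun(y), (0.0, horizon), y_relax,
                method="LSODA", rtol=1e-12, atol=np.abs(seed) * 1e-12 + 1e-16,
            )
            if not relaxed.success:
                break
            y_relax = relaxed.y[:, -1]
            sol, y_ss, res = solve_from(y_relax[free_ix] / scale[free_ix])
            if sol.success and res <= residual_tol:
                break
    if not sol.success or res > residual_tol:
        raise SolverError(
            f"steady-state solve did not converge (best residual {res:.3g} mM/s)",
            state=y_ss,
        )
    jac = _finite_difference_jacobian(rhs_fun, y_ss, free_ix)
    eig = np.linalg.eigvals(jac)
    return SteadyStateReport(
        state=y_ss,
        residual_norm=res,
        jacobian_eigenvalues=eig,
        stable=bool(np.all(eig.real < 0.0)),
        converged=bool(sol.success),
        free_states=free_names,
    )


def _finite_difference_jacobian(
    fun: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    free_ix: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central-difference Jacobian of the free subsystem, per-state steps."""
    n = free_ix.size
    jac = np.empty((n, n))
    for k, j in enumerate(free_ix):
        step = rel_step * max(abs(y[j]), 1e-6)
        yp = y.copy()
        yp[j] += step
        ym = y.copy()
        ym[j] -= step
        jac[:, k] = (fun(yp)[free_ix] - fun(ym)[free_ix]) / (2.0 * step)
    return jac


def stability_check(report, tol: float = 0.0) -> StabilityVerdict:
    """Classify a fixed point from its Jacobian spectrum.

    Stable iff every eigenvalue has a strictly negative real part; marginal
    spectra (zero real part, e.g. a pure rotation) are flagged unstable by
    convention.  Accepts a :class:`SteadyStateReport`, an eigenvalue array or
    a square Jacobian matrix.
    """
    if isinstance(report, SteadyStateReport):
        eig = report.jacobian_eigenvalues
    else:
        arr = np.asarray(report)
        eig = np.linalg.eigvals(arr) if arr.ndim == 2 else arr.astype(complex)
    max_re = float(np.max(eig.real))
    return StabilityVerdict(stable=bool(max_re < -tol), max_real_part=max_re, eigenvalues=eig)
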