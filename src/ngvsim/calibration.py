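"""Two-tier parameter determination.

Tier 1 (:func:`steady_state_constrain`): the "constrained" rate capacities
are solved algebraically so that the published resting concentrations are a
fixed point.  The resting balances alone do not pin every capacity, so the
solve is closed with three imposed partition fractions that encode the
model's compartmentalization assumptions: astrocytes take most of the
glucose, neurons most of the oxygen, and only a small share of astrocytic
glucose arrives directly from the capillary.  The cell-membrane lactate
capacities are kept as given: their resting concentration gradients are
smaller than the printed rounding of the resting state, which makes solving
for them ill-conditioned.

Tier 2 (:func:`fit_free_parameters`): the "optimized" kinetic constants are
fitted by a downhill-simplex (Nelder-Mead) least-squares match of simulated
relative-NADH transients against reference curves, re-running tier 1 and a
steady-state stability check for every candidate.  Reference data points are
first smoothed into continuous curves by a sum-of-exponentials fit
(:func:`smooth_reference_curves`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, least_squares

from . import fluxes as fx
from .engine import SteadyStateReport, find_steady_state, integrate, stability_check
from .errors import ConfigError, ModelDomainError, NgvError, SolverError
from .observables import nadh_transients
from .params import ParameterSet
from .state import STATE_INDEX, resting_state
from .stimulus import ScenarioSpec

__all__ = [
    "TargetCurves",
    "FitResult",
    "PartitionFractions",
    "steady_state_constrain",
    "smooth_reference_curves",
    "sum_of_exponentials_fit",
    "fit_free_parameters",
]

log = logging.getLogger(__name__)

CURVE_NAMES = ("astro_cyto", "neuron_mito", "tissue")


@dataclass
class TargetCurves:
    """Relative-NADH reference curves (percent, zero baseline) on one grid."""

    t: np.ndarray
    curves: dict[str, np.ndarray]
    stim_end: float = 20.0
    provenance: str = "user"  #: 'fixture' or 'user'
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name, v in self.curves.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.t.shape:
                raise ConfigError(f"curve {name!r} does not match the time grid")
            self.curves[name] = v

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_s": self.t})
        for name in CURVE_NAMES:
            if name in self.curves:
                df[f"{name}_pct"] = self.curves[name]
        df.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, stim_end: float = 20.0) -> "TargetCurves":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ConfigError(f"{path}: missing 'time_s' column")
        curves = {
            name: df[f"{name}_pct"].to_numpy()
            for name in CURVE_NAMES
            if f"{name}_pct" in df.columns
        }
        if not curves:
            raise ConfigError(f"{path}: no *_pct curve columns found")
        return cls(t=df["time_s"].to_numpy(), curves=curves,
                   stim_end=stim_end, provenance="user")


@dataclass(frozen=True)
class PartitionFractions:
    """Imposed resting partitions closing the constrained-parameter solve."""

    glc_neuron_share: float = 0.33    #: neuronal share of total glucose uptake
    o2_neuron_share: float = 0.75     #: neuronal share of total oxygen uptake
    glc_astro_cap_fraction: float = 0.023  #: astro glucose taken directly from capillary


# ----------------------------------------------------------------------
# tier 1: algebraic constraints
# ----------------------------------------------------------------------
def steady_state_constrain(
    rest_targets: np.ndarray | Mapping[str, float] | None = None,
    params: ParameterSet | None = None,
    free_subset: Iterable[str] | None = None,
    partitions: PartitionFractions | None = None,
) -> tuple[ParameterSet, dict[str, float]]:
    """Solve the constrained parameters from resting flux balances.

    Parameters
    ----------
    rest_targets : state vector or name->value mapping
        Target resting concentrations (defaults to the published values).
    params : ParameterSet
        Source of the fixed and optimized parameters (and of any constrained
        parameter kept as given).
    free_subset : iterable of parameter names, optional
        Restrict which solved values are applied; defaults to every parameter
        the solve covers.  Names outside the constrained group are rejected.

    Returns the updated parameter set and the dict of solved values.  Raises
    :class:`ConfigError` naming the violated balance when targets admit no
    positive solution.
    """
    p = params or ParameterSet()
    partitions = partitions or PartitionFractions()
    if rest_targets is None:
        y = resting_state()
    elif isinstance(rest_targets, Mapping):
        y = resting_state()
        for k, v in rest_targets.items():
            if k not in STATE_INDEX:
                raise ConfigError(f"unknown state {k!r} in rest targets")
            y[STATE_INDEX[k]] = float(v)
    else:
        y = np.asarray(rest_targets, dtype=float)
    s = {n: float(y[i]) for n, i in STATE_INDEX.items()}

    solved: dict[str, float] = {}

    def sat(c: float, k: float) -> float:
        return c / (c + k)

    def carrier_gradient(a: float, b: float, kt: float, balance: str) -> float:
        d = sat(a, kt) - sat(b, kt)
        if abs(d) < 1e-12:
            raise ConfigError(
                f"resting balance {balance!r}: zero carrier gradient, "
                "cannot solve for a capacity"
            )
        return d

    def positive(name: str, value: float, balance: str) -> float:
        if not np.isfinite(value) or value <= 0.0:
            raise ConfigError(
                f"resting balance {balance!r} yields non-positive {name} = {value:g}"
            )
        solved[name] = value
        return value

    aden = {x: fx.adenylate_closure(s[f"ATP_{x}"], p) for x in "ng"}
    vol = {"n": p.v_n, "g": p.v_g}

    # total supplies fixed by the baseline blood flow (per tissue volume)
    j_glc_tot = 2.0 * p.f_0 * (p.glc_a - s["GLC_c"])
    j_o2_tot = 2.0 * p.f_0 * (p.o2_a - s["O2_c"])
    if j_glc_tot <= 0.0 or j_o2_tot <= 0.0:
        raise ConfigError("arterial supply must exceed capillary content at rest")
    share = {"n": partitions.glc_neuron_share, "g": 1.0 - partitions.glc_neuron_share}
    o2_share = {"n": partitions.o2_neuron_share, "g": 1.0 - partitions.o2_neuron_share}

    j_hk: dict[str, float] = {}
    j_mout: dict[str, float] = {}
    j_ldh: dict[str, float] = {}
    eq_o2 = p.k_o2 * (p.hb_op / s["O2_c"] - 1.0) ** (-1.0 / p.n_hb)

    for x in "ng":
        atp, adp = s[f"ATP_{x}"], aden[x].adp
        glc, gap, pep, pyr = s[f"GLC_{x}"], s[f"GAP_{x}"], s[f"PEP_{x}"], s[f"PYR_{x}"]
        nadh_c, nadh_m, lac = s[f"NADH_cyto_{x}"], s[f"NADH_mito_{x}"], s[f"LAC_{x}"]

        j_hk[x] = share[x] * j_glc_tot / vol[x]
        inh = 1.0 + (atp / p.k_i_atp) ** p.n_h
        positive(f"k_hkpfk_{x}", j_hk[x] * inh / (atp * sat(glc, p.k_g)),
                 f"GLC_{x} consumption")

        j_mout[x] = o2_share[x] * j_o2_tot / (0.6 * vol[x])
        positive(
            f"vmax_out_{x}",
            j_mout[x] / (
                sat(s[f"O2_{x}"], p.k_o2_mito)
                * sat(adp, getattr(p, f"k_m_adp_{x}"))
                * sat(nadh_m, getattr(p, f"k_m_nadh_{x}"))
            ),
            f"O2_{x} balance",
        )
        positive(f"ps_cap_v{x}", 0.6 * j_mout[x] / (eq_o2 - s[f"O2_{x}"]),
                 f"O2_{x} exchange")

        j_pgk = 2.0 * j_hk[x]
        positive(f"k_pgk_{x}", j_pgk / (gap * adp * (p.n_tot - nadh_c) / nadh_c),
                 f"GAP_{x} balance")
        positive(f"k_pk_{x}", j_pgk / (pep * adp), f"PEP_{x} balance")

        # mitochondrial NADH balance combined with the pyruvate balance fixes
        # the LDH net flux: 10 J_HKPFK - 5 J_LDH = J_mito_out
        j_ldh[x] = 2.0 * j_hk[x] - j_mout[x] / 5.0
        kp = getattr(p, f"kp_ldh_{x}")
        positive(f"km_ldh_{x}",
                 (kp * pyr * nadh_c - j_ldh[x]) / (lac * (p.n_tot - nadh_c)),
                 f"LAC_{x} production balance")

        j_sh = j_pgk - j_ldh[x]
        r_minus = nadh_c / (p.n_tot - nadh_c)
        r_plus = (p.n_tot - nadh_m) / nadh_m
        positive(
            f"t_nadh_{x}",
            j_sh / (
                r_minus / (r_minus + getattr(p, f"m_cyto_{x}"))
                * r_plus / (r_plus + getattr(p, f"m_mito_{x}"))
            ),
            f"NADH_cyto_{x} balance",
        )

        j_min = j_pgk - j_ldh[x]  # pyruvate balance: J_PK - J_LDH
        nad_m = p.n_tot - nadh_m
        positive(
            f"vmax_in_{x}",
            j_min / (sat(pyr, p.k_m_mito) * nad_m / (nad_m + getattr(p, f"k_m_nad_{x}"))),
            f"PYR_{x} balance",
        )

        pcr = s[f"PCr_{x}"]
        positive(
            f"km_ck_{x}",
            getattr(p, f"kp_ck_{x}") * adp * pcr / (atp * (p.c_tot - pcr)),
            f"PCr_{x} equilibrium",
        )

    # glucose carrier capacities
    positive("tmax_glc_en",
             j_hk["n"] / carrier_gradient(s["GLC_e"], s["GLC_n"], p.kt_glc_en, "GLC_n"),
             "GLC_n supply")
    j_glc_cg = partitions.glc_astro_cap_fraction * j_hk["g"]
    j_glc_eg = j_hk["g"] - j_glc_cg
    positive("tmax_glc_cg",
             j_glc_cg / carrier_gradient(s["GLC_c"], s["GLC_g"], p.kt_glc_cg, "GLC_g"),
             "GLC_g capillary route")
    positive("tmax_glc_eg",
             j_glc_eg / carrier_gradient(s["GLC_e"], s["GLC_g"], p.kt_glc_eg, "GLC_g"),
             "GLC_g extracellular route")
    j_glc_ce = j_glc_eg / p.r_eg + j_hk["n"] / p.r_en  # per extracellular volume
    positive("tmax_glc_ce",
             j_glc_ce / carrier_gradient(s["GLC_c"], s["GLC_e"], p.kt_glc_ce, "GLC_e"),
             "GLC_e balance")

    # housekeeping ATPase loads from the ATP balances (CK is at equilibrium)
    pump_n = p.sm_vn * p.k_pump_n * s["ATP_n"] * s["Na_n"] / (1.0 + s["ATP_n"] / p.k_m_pump)
    pump_g = p.sm_vg * p.k_pump_g * s["ATP_g"] * s["Na_g"] / (1.0 + s["ATP_g"] / p.k_m_pump)
    # -2 J_HKPFK + J_PGK + J_PK reduces to +2 J_HKPFK at rest
    positive("j_atpases_n",
             2.0 * j_hk["n"] - pump_n + 3.6 * j_mout["n"],
             "ATP_n balance")
    positive("j_atpases_g",
             2.0 * j_hk["g"] - 1.75 * pump_g + 0.75 * p.j_pump0_g + 3.6 * j_mout["g"],
             "ATP_g balance")

    # extracellular and capillary lactate balances
    j_lac_ne = j_ldh["n"]                       # neuronal lactate balance
    j_lac_gc = fx.carrier_flux(s["LAC_g"], s["LAC_c"], p.tmax_lac_gc, p.kt_lac_gc)
    j_lac_ge = j_ldh["g"] - j_lac_gc            # astrocytic lactate balance
    j_lac_ec = j_lac_ne / p.r_en + j_lac_ge / p.r_eg
    positive("tmax_lac_ec",
             j_lac_ec / carrier_gradient(s["LAC_e"], s["LAC_c"], p.kt_lac_ec, "LAC_e"),
             "LAC_e balance")
    lac_a = s["LAC_c"] - (j_lac_ec / p.r_ce + j_lac_gc / p.r_cg) * p.v_cap / (2.0 * p.f_0)
    positive("lac_a", lac_a, "LAC_c balance")

    if free_subset is None:
        applied = solved
    else:
        free_subset = list(free_subset)
        constrained = set(p.names("constrained"))
        bad = [n for n in free_subset if n not in constrained]
        if bad:
            raise ConfigError(f"not constrained parameters: {bad}")
        missing = [n for n in free_subset if n not in solved]
        if missing:
            raise ConfigError(
                f"no balance equation solves for {missing} "
                "(cell-membrane lactate capacities are kept as given)"
            )
        applied = {n: solved[n] for n in free_subset}
    return p.replace(**applied), solved


# ----------------------------------------------------------------------
# reference-curve smoothing
# ----------------------------------------------------------------------
def sum_of_exponentials_fit(
    t: np.ndarray,
    y: np.ndarray,
    n_terms: int = 2,
) -> tuple[dict, np.ndarray]:
    """Least-squares fit of ``c0 + sum_i a_i exp(-t/tau_i)`` to points.

    The time constants are optimized in log space with the amplitudes and
    offset eliminated by linear least squares at every step (variable
    projection); a few spread-out initializations guard against local minima.
    Returns ``({"offset", "amplitudes", "taus", "residual"}, fitted_values)``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2 * n_terms + 2:
        raise ConfigError(
            f"need at least {2 * n_terms + 2} points to fit {n_terms} exponentials"
        )
    span = max(t.max() - t.min(), 1e-9)
    t0 = t - t.min()

    def design(log_taus: np.ndarray) -> np.ndarray:
        taus = np.exp(log_taus)
        cols = [np.ones_like(t0)] + [np.exp(-t0 / tau) for tau in taus]
        return np.column_stack(cols)

    def residual(log_taus: np.ndarray) -> np.ndarray:
        a_mat = design(log_taus)
        coef, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
        return a_mat @ coef - y

    best = None
    inits = [
        np.log(np.geomspace(span / 20.0, span / 1.5, n_terms)),
        np.log(np.geomspace(span / 50.0, span / 4.0, n_terms)),
        np.log(np.geomspace(span / 8.0, span, n_terms)),
    ]
    for x0 in inits:
        sol = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    a_mat = design(best.x)
    if np.linalg.matrix_rank(a_mat) < a_mat.shape[1]:
        raise ConfigError("rank-deficient exponential fit (degenerate time constants)")
    coef, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
    fitted = a_mat @ coef
    order = np.argsort(np.exp(best.x))
    info = {
        "offset": float(coef[0]),
        "amplitudes": np.asarray(coef[1:])[order],
        "taus": np.exp(best.x)[order],
        "residual": float(np.sqrt(np.mean((fitted - y) ** 2))),
        "t_ref": float(t.min()),
    }
    return info, fitted


def smooth_reference_curves(
    points: TargetCurves,
    n_terms: int = 2,
    grid: np.ndarray | None = None,
) -> tuple[TargetCurves, dict]:
    """Smooth sampled reference points into continuous curves.

    Each curve is fitted with a sum of ``n_terms`` exponentials plus offset
    and evaluated on ``grid`` (default: the input grid refined to 0.1 s).
    A constant series reduces to its offset with zero residual.
    """
    if grid is None:
        grid = np.arange(points.t.min(), points.t.max() + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    curves: dict[str, np.ndarray] = {}
    fit_info: dict[str, dict] = {}
    for name, y in points.curves.items():
        if np.ptp(y) == 0.0:
            curves[name] = np.full_like(grid, y[0])
            fit_info[name] = {"offset": float(y[0]), "amplitudes": np.zeros(0),
                              "taus": np.zeros(0), "residual": 0.0}
            continue
        info, _ = sum_of_exponentials_fit(points.t, y, n_terms=n_terms)
        g0 = grid - info["t_ref"]
        vals = info["offset"] + sum(
            a * np.exp(-g0 / tau) for a, tau in zip(info["amplitudes"], info["taus"])
        )
        curves[name] = vals
        fit_info[name] = info
    return (
        TargetCurves(t=grid, curves=curves, stim_end=points.stim_end,
                     provenance=points.provenance, meta={"smoothed": True}),
        fit_info,
    )


# ----------------------------------------------------------------------
# tier 2: simplex fit
# ----------------------------------------------------------------------
@dataclass
class FitResult:
    """Outcome of the downhill-simplex calibration."""

    params: ParameterSet
    values: dict[str, float]
    sse: float
    n_iterations: int
    n_evaluations: int
    converged: bool
    steady_state: SteadyStateReport
    stable: bool


def _model_curves(
    params: ParameterSet,
    scenario: ScenarioSpec,
    sim_kwargs: Mapping,
) -> tuple[dict[str, np.ndarray], np.ndarray, SteadyStateReport]:
    report = find_steady_state(params)
    traj = integrate(scenario, params, y0=report.state, **dict(sim_kwargs))
    curves = nadh_transients(traj)
    return {k: v.values for k, v in curves.items()}, traj.t, report


def fit_free_parameters(
    targets: TargetCurves,
    free_names: Sequence[str],
    init: ParameterSet | None = None,
    scenario: ScenarioSpec | None = None,
    *,
    reconstrain: bool = True,
    rest_targets=None,
    partitions: PartitionFractions | None = None,
    grid_dt: float = 0.5,
    maxiter: int | None = None,
    maxfev: int | None = None,
    xatol: float = 1e-6,
    sim_kwargs: Mapping | None = None,
) -> FitResult:
    """Nelder-Mead least-squares fit of free parameters to NADH target curves.

    The optimized parameters are searched in log space (enforcing
    positivity).  Each candidate re-solves the constrained parameters
    (``reconstrain=True``), recomputes the steady state, verifies its
    stability and simulates the scenario; candidates whose simulation fails
    are rejected with a penalty.  The error is the unweighted sum of squared
    differences on a common ``grid_dt`` grid over every curve present in
    ``targets``.
    """
    from .stimulus import make_scenario

    init = init or ParameterSet()
    scenario = scenario or make_scenario("in_vitro")
    sim_kwargs = dict(sim_kwargs or {})
    free_names = list(free_names)
    optimizable = set(init.names("optimized"))
    bad = [n for n in free_names if n not in optimizable]
    if bad:
        raise ConfigError(f"not in the optimized parameter group: {bad}")

    grid = np.arange(0.0, min(targets.t.max(), scenario.total_duration) + 1e-9, grid_dt)
    target_interp = {
        name: np.interp(grid, targets.t, vals) for name, vals in targets.curves.items()
    }
    n_eval = 0
    penalty = 1e12

    def build(theta: np.ndarray) -> ParameterSet:
        p = init.replace(**{n: math.exp(v) for n, v in zip(free_names, theta)})
        if reconstrain:
            p, _ = steady_state_constrain(rest_targets, p, partitions=partitions)
        return p

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            p = build(theta)
            model, t_model, report = _model_curves(p, scenario, sim_kwargs)
            if not stability_check(report).stable:
                raise SolverError("candidate steady state is unstable")
        except NgvError as err:
            log.warning("candidate rejected: %s", err)
            return penalty
        sse = 0.0
        for name, tgt in target_interp.items():
            sim = np.interp(grid, t_model, model[name])
            sse += float(np.sum((sim - tgt) ** 2))
        return sse

    if not free_names:
        p = build(np.empty(0))
        model, t_model, report = _model_curves(p, scenario, sim_kwargs)
        sse = sum(
            float(np.sum((np.interp(grid, t_model, model[n]) - tgt) ** 2))
            for n, tgt in target_interp.items()
        )
        return FitResult(
            params=p, values={}, sse=sse, n_iterations=0, n_evaluations=1,
            converged=True, steady_state=report,
            stable=stability_check(report).stable,
        )

    x0 = np.array([math.log(getattr(init, n)) for n in free_names])
    options = {"xatol": xatol, "fatol": 1e-12, "disp": False}
    if maxiter is not None:
        options["maxiter"] = maxiter
    if maxfev is not None:
        options["maxfev"] = maxfev
    res = minimize(objective, x0, method="Nelder-Mead", options=options)
    p_final = build(res.x)
    model, t_model, report = _model_curves(p_final, scenario, sim_kwargs)
    return FitResult(
        params=p_final,
        values={n: math.exp(v) for n, v in zip(free_names, res.x)},
        sse=float(res.fun),
        n_iterations=int(res.nit),
        n_evaluations=n_eval,
        converged=bool(res.success),
        steady_state=report,
        stable=stability_check(report).stable,
    )
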