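"""Run configuration and output bundling.

A :class:`RunConfig` resolves, before any simulation starts, to a scenario,
a parameter set and solver settings.  Configuration files are YAML or JSON;
unknown keys are rejected with a nearest-name suggestion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from ._version import __version__
from .calibration import TargetCurves
from .engine import Trajectory
from .errors import ConfigError
from .fixtures import FixtureSettings
from .params import ParameterSet, _check_keys
from .stimulus import ScenarioSpec, make_scenario

__all__ = ["RunConfig", "load_config", "save_outputs"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    scenario: str = "in_vitro"
    stim_duration: float | None = None
    total_duration: float | None = None
    flow_delay: float | None = None
    flow_overrides: dict[str, float] = field(default_factory=dict)
    stimulus_overrides: dict[str, float] = field(default_factory=dict)
    param_file: str | None = None
    param_overrides: dict[str, float] = field(default_factory=dict)
    rtol: float = 1e-6
    max_step_spiking: float = 1e-4
    dt_fine: float = 1e-3
    dt_coarse: float = 0.1
    out_dir: str = "ngv-out"
    fixture: dict[str, Any] = field(default_factory=dict)

    def resolve(self) -> tuple[ScenarioSpec, ParameterSet]:
        """Validate and build the scenario and parameter set."""
        params = (
            ParameterSet.load(self.param_file) if self.param_file else ParameterSet()
        )
        if self.param_overrides:
            params = params.replace(**self.param_overrides)
        overrides: dict[str, Any] = {}
        if self.stim_duration is not None:
            overrides["stim_duration"] = self.stim_duration
        if self.total_duration is not None:
            overrides["total_duration"] = self.total_duration
        if self.flow_delay is not None:
            overrides["flow_delay"] = self.flow_delay
        if self.flow_overrides:
            overrides["flow"] = dict(self.flow_overrides)
        if self.stimulus_overrides:
            overrides["stimulus"] = dict(self.stimulus_overrides)
        scenario = make_scenario(_canonical_kind(self.scenario), **overrides)
        return scenario, params

    def fixture_settings(self) -> FixtureSettings:
        known = {f.name for f in dataclasses.fields(FixtureSettings)}
        _check_keys(self.fixture, {k: None for k in known}, what="fixture setting")
        return FixtureSettings(**self.fixture)

    def solver_kwargs(self) -> dict[str, float]:
        return {
            "rtol": self.rtol,
            "max_step_spiking": self.max_step_spiking,
            "dt_fine": self.dt_fine,
            "dt_coarse": self.dt_coarse,
        }

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.as_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=1))


_KIND_ALIASES = {
    "invitro": "in_vitro",
    "in_vitro": "in_vitro",
    "rodent": "in_vivo_rodent",
    "in_vivo_rodent": "in_vivo_rodent",
    "human": "in_vivo_human",
    "in_vivo_human": "in_vivo_human",
}


def _canonical_kind(kind: str) -> str:
    try:
        return _KIND_ALIASES[kind]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {kind!r}; choose from invitro, rodent, human"
        ) from None


def load_config(path: str | Path) -> RunConfig:
    """Load and strictly validate a YAML/JSON run configuration."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: configuration must be a mapping")
    known = {f.name: None for f in dataclasses.fields(RunConfig)}
    _check_keys(doc, known, what="config key")
    cfg = RunConfig(**doc)
    # fail early on anything that cannot resolve
    cfg.resolve()
    cfg.fixture_settings()
    return cfg


def save_outputs(
    traj: Trajectory,
    observables: Mapping[str, Any] | None,
    report: Mapping[str, Any] | None,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write the standard output bundle of a run.

    Produces ``trajectory.csv`` (states + fluxes + inputs, with observable
    columns appended when given), ``summary.json`` (headline metrics) and
    ``manifest.json`` (parameters, scenario, tolerances, versions).  Returns
    the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frame = traj.to_frame(include_fluxes=True)
    if observables:
        for name, series in observables.items():
            values = getattr(series, "values", series)
            if len(values) == len(frame):
                frame[name] = values
    paths["trajectory"] = out / "trajectory.csv"
    frame.to_csv(paths["trajectory"], index=False, float_format="%.17g")

    manifest = traj.manifest(extra={"config": config.as_dict() if config else None})
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))

    if report is not None:
        paths["summary"] = out / "summary.json"
        paths["summary"].write_text(json.dumps(report, indent=1, default=float))
    return paths
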