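"""Scenario configuration: packaged fixtures, file loading, full reports.

A scenario bundles a complete parameter set, an initial state and the
integration settings for one run. Three scenarios ship with the package:

``table1_baseline``
    The baseline parameter table with the ranged entries pinned.
``case1_r0_lt_1``
    Subthreshold scenario (R0 ≈ 0.8684); addiction dies out.
``case2_r0_gt_1``
    Supercritical scenario (R0 ≈ 1.3372); addiction persists at the
    endemic equilibrium.

Configuration files are flat YAML/JSON documents with a versioned schema;
unknown keys are rejected, and an explicit ``extends: <packaged name>``
fills unspecified parameters from the named base scenario.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .equilibria import compute_R0, dfe, eep, strength_number, phi_star
from .model import InvalidInputError, ModelParameters, StateVector
from .sensitivity import nfsi_table
from .simulation import detect_steady_state, integrate
from .stability import bifurcation_coefficients, dfe_stability, eep_stability

__all__ = ["Scenario", "PACKAGED_SCENARIOS", "load_scenario", "load_config", "save_config", "run_report"]

PACKAGED_SCENARIOS = ("table1_baseline", "case1_r0_lt_1", "case2_r0_gt_1")

_SCHEMA_VERSION = 1
_ALLOWED_KEYS = {"schema", "name", "note", "extends", "params", "initial_state", "h", "t_end"}


@dataclass(frozen=True)
class Scenario:
    name: str
    params: ModelParameters
    state0: StateVector
    h: float = 0.001
    t_end: float = 500.0
    note: str = ""

    def as_dict(self) -> dict[str, Any]:
        return {
            "schema": _SCHEMA_VERSION,
            "name": self.name,
            "note": self.note,
            "params": self.params.as_dict(),
            "initial_state": list(self.state0),
            "h": self.h,
            "t_end": self.t_end,
        }


def _validate_document(doc: Any, source: str) -> Mapping[str, Any]:
    if not isinstance(doc, Mapping):
        raise InvalidInputError(f"{source}: scenario document must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - _ALLOWED_KEYS
    if unknown:
        raise InvalidInputError(f"{source}: unknown key(s) {sorted(unknown)}")
    if doc.get("schema", _SCHEMA_VERSION) != _SCHEMA_VERSION:
        raise InvalidInputError(f"{source}: unsupported schema version {doc['schema']!r}")
    return doc


def _scenario_from_document(doc: Mapping[str, Any], source: str) -> Scenario:
    doc = _validate_document(doc, source)
    params_doc = dict(doc.get("params", {}))
    base = doc.get("extends")
    if base is not None:
        if base not in PACKAGED_SCENARIOS:
            raise InvalidInputError(f"{source}: extends={base!r} is not a packaged scenario {PACKAGED_SCENARIOS}")
        merged = load_scenario(base).params.as_dict()
        merged.update(params_doc)
        params_doc = merged
    try:
        params = ModelParameters.from_dict(params_doc)
    except (InvalidInputError, ValueError) as exc:
        raise InvalidInputError(f"{source}: {exc}") from exc
    state0 = StateVector.from_iterable(doc.get("initial_state", (100, 1, 5, 2, 0, 10)))
    if any(c < 0 for c in state0):
        raise InvalidInputError(f"{source}: initial state components must be nonnegative, got {tuple(state0)}")
    return Scenario(
        name=str(doc.get("name", Path(source).stem)),
        params=params,
        state0=state0,
        h=float(doc.get("h", 0.001)),
        t_end=float(doc.get("t_end", 500.0)),
        note=str(doc.get("note", "")).strip(),
    )


def load_scenario(name: str) -> Scenario:
    """Load a packaged scenario by name."""
    if name not in PACKAGED_SCENARIOS:
        raise InvalidInputError(f"unknown scenario {name!r}; packaged scenarios: {PACKAGED_SCENARIOS}")
    resource = importlib.resources.files("smad.data").joinpath(f"{name}.yaml")
    doc = yaml.safe_load(resource.read_text())
    return _scenario_from_document(doc, source=name)


def load_config(path) -> Scenario:
    """Load and validate a scenario from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    text = path.read_text()
    try:
        doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise InvalidInputError(f"{path}: parse failure: {exc}") from exc
    return _scenario_from_document(doc, source=str(path))


def save_config(scenario: Scenario, path) -> None:
    """Write a scenario to YAML or JSON (by extension); round-trips exactly."""
    path = Path(path)
    doc = scenario.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _state_dict(state) -> dict[str, float]:
    return {k: float(v) for k, v in zip(("S", "E", "I1", "I2", "R", "Q"), state)}


def run_report(scenario: Scenario, seed: int = 0, simulate: bool = True) -> dict[str, Any]:
    """One JSON-serialisable summary of everything the package computes.

    Covers the reproduction number, both equilibria with residuals, local
    stability verdicts, the bifurcation normal-form coefficients, the
    NFSI elasticity table and (optionally) the simulated steady state.
    Deterministic for a fixed scenario; ``seed`` is recorded for
    provenance (no step here is stochastic).
    """
    p = scenario.params
    R0 = compute_R0(p)
    dfe_report = dfe(p)
    dfe_stab = dfe_stability(p)
    eep_report = eep(p)
    bif = bifurcation_coefficients(p)
    report: dict[str, Any] = {
        "meta": {"package_version": __version__, "seed": seed, "scenario": scenario.name},
        "R0": R0,
        "strength_number": strength_number(p),
        "phi_star": bif.phi_star,
        "dfe": {
            "state": _state_dict(dfe_report.state),
            "residual": dfe_report.residual,
            "verdict": dfe_stab.verdict,
            "eigenvalues": [[z.real, z.imag] for z in dfe_stab.eigenvalues],
            "max_real_part": dfe_stab.max_real_part,
        },
        "bifurcation": {"a": bif.a, "b": bif.b, "phi_star": bif.phi_star},
        "nfsi": nfsi_table(p).indices,
    }
    if eep_report is not None:
        eep_stab = eep_stability(p)
        report["eep"] = {
            "state": _state_dict(eep_report.state),
            "residual": eep_report.residual,
            "verdict": eep_stab.verdict,
            "eigenvalues": [[z.real, z.imag] for z in eep_stab.eigenvalues],
            "max_real_part": eep_stab.max_real_part,
        }
    if simulate:
        traj = integrate(p, scenario.state0, h=scenario.h, t_end=scenario.t_end)
        steady = detect_steady_state(traj, tol=1e-6, window=10)
        report["simulation"] = {
            "h": scenario.h,
            "t_end": scenario.t_end,
            "initial_state": _state_dict(scenario.state0),
            "final_state": _state_dict(traj.final_state),
            "steady_state": _state_dict(steady) if steady is not None else None,
            "max_N": float(np.max(traj.states.sum(axis=1))),
        }
    return report
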