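"""Run configuration: one JSON/YAML document describing a reproducible run.

Every field is optional; omitted fields fall back to the documented standard
conditions (constants), the standard stimulus, the overlap condition and the
default solver settings.  Validation is strict — unknown keys are errors —
and reports every offending field at once rather than the first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError
from .parameters import StandardConstants, complete_constants
from .stimulus import CalciumTransient, make_standard_transient
from .transient import (
    DEFAULT_ATOL,
    DEFAULT_DT_OUT,
    DEFAULT_HORIZON,
    DEFAULT_RTOL,
    Condition,
)

_CONSTANT_KEYS = (
    "K0p", "K1", "K2", "K3", "K4", "K5",
    "km0", "km1", "km2", "km3", "km4", "km5", "alpha", "n",
)
_INDEPENDENT_KEYS = (
    "K0p", "K1", "K2", "K4", "km0", "km1", "km2", "km3", "km4", "km5",
    "alpha", "n",
)
_STIMULUS_KEYS = ("kind", "amplitude", "t_peak", "decay_rate", "baseline", "table")
_SOLVER_KEYS = ("rtol", "atol", "horizon", "dt_out")


def _as_float(value):
    """Coerce a config scalar to float, tolerating YAML's '1e-08' strings."""
    if isinstance(value, bool):
        raise TypeError("boolean is not a number")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        return float(value)
    raise TypeError(f"{value!r} is not a number")
#: relative tolerance for a user-supplied K3/K5 against the ladder
_LADDER_RTOL = 1e-6


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    horizon: float = DEFAULT_HORIZON
    dt_out: float = DEFAULT_DT_OUT


@dataclass(frozen=True)
class RunConfig:
    """Validated inputs of one reproducible run."""

    constants: StandardConstants = field(default_factory=complete_constants)
    stimulus: CalciumTransient = field(default_factory=make_standard_transient)
    condition: Condition = field(default_factory=Condition.overlap)
    solver: SolverSettings = field(default_factory=SolverSettings)
    outputs: str = "."
    seed: int = None

    def to_dict(self) -> dict:
        stim = self.stimulus
        stim_doc = {
            "kind": stim.kind,
            "amplitude": stim.amplitude,
            "t_peak": stim.t_peak,
            "decay_rate": stim.decay_rate,
            "baseline": stim.baseline,
        }
        if stim.kind == "tabulated":
            stim_doc["table"] = [list(p) for p in stim.table]
        doc = {
            "constants": self.constants.to_dict(),
            "stimulus": stim_doc,
            "condition": {"name": self.condition.name, "K0p": self.condition.k0p},
            "solver": dataclasses.asdict(self.solver),
            "outputs": self.outputs,
        }
        if self.seed is not None:
            doc["seed"] = int(self.seed)
        return doc


def _parse_constants(doc, errors) -> StandardConstants:
    if not isinstance(doc, dict):
        errors.append("constants: must be a mapping")
        return complete_constants()
    unknown = set(doc) - set(_CONSTANT_KEYS)
    for key in sorted(unknown):
        errors.append(f"constants.{key}: unknown key")
    kwargs = {}
    for key in _INDEPENDENT_KEYS:
        if key in doc:
            try:
                kwargs[key] = _as_float(doc[key])
            except (TypeError, ValueError):
                errors.append(f"constants.{key}: must be a number")
    try:
        constants = complete_constants(**kwargs)
    except Exception as err:  # positivity violations, collected not raised
        errors.append(f"constants: {err}")
        return complete_constants()
    # explicitly supplied K3/K5 must match the thermodynamic ladder
    for key in ("K3", "K5"):
        try:
            supplied = _as_float(doc[key]) if key in doc else None
        except (TypeError, ValueError):
            supplied = None
        if supplied is not None:
            expected = getattr(constants, key)
            if abs(supplied - expected) > _LADDER_RTOL * expected:
                errors.append(
                    f"constants.{key}: {supplied} violates the thermodynamic "
                    f"constraint K1/K3 = K3/K5 = K2/K4 (expected {expected:g})"
                )
    return constants


def _parse_stimulus(doc, errors) -> CalciumTransient:
    if not isinstance(doc, dict):
        errors.append("stimulus: must be a mapping")
        return make_standard_transient()
    for key in sorted(set(doc) - set(_STIMULUS_KEYS)):
        errors.append(f"stimulus.{key}: unknown key")
    kind = doc.get("kind", "analytic")
    try:
        if kind == "tabulated":
            table = doc.get("table")
            if not table:
                errors.append("stimulus.table: required for tabulated kind")
                return make_standard_transient()
            return CalciumTransient(kind="tabulated",
                                    table=tuple(tuple(p) for p in table))
        kwargs = {k: _as_float(doc[k]) for k in
                  ("amplitude", "t_peak", "decay_rate", "baseline") if k in doc}
        return make_standard_transient(**kwargs)
    except Exception as err:
        errors.append(f"stimulus: {err}")
        return make_standard_transient()


def _parse_condition(doc, errors) -> Condition:
    if isinstance(doc, str):
        doc = {"name": doc}
    if not isinstance(doc, dict):
        errors.append("condition: must be a name or mapping")
        return Condition.overlap()
    for key in sorted(set(doc) - {"name", "K0p"}):
        errors.append(f"condition.{key}: unknown key")
    try:
        return Condition.from_name(doc.get("name", "overlap"), doc.get("K0p"))
    except Exception as err:
        errors.append(f"condition: {err}")
        return Condition.overlap()


def _parse_solver(doc, errors) -> SolverSettings:
    if not isinstance(doc, dict):
        errors.append("solver: must be a mapping")
        return SolverSettings()
    for key in sorted(set(doc) - set(_SOLVER_KEYS)):
        errors.append(f"solver.{key}: unknown key")
    kwargs = {}
    for key in _SOLVER_KEYS:
        if key in doc:
            try:
                value = _as_float(doc[key])
                if value <= 0:
                    raise ValueError
                kwargs[key] = value
            except (TypeError, ValueError):
                errors.append(f"solver.{key}: must be a positive number")
    return SolverSettings(**kwargs)


def parse_config(document: dict) -> RunConfig:
    """Validate a parsed JSON/YAML document into a :class:`RunConfig`.

    Raises :class:`ValidationError` carrying *every* offending field.
    """
    document = {} if document is None else document
    errors = []
    if not isinstance(document, dict):
        raise ValidationError(["configuration root must be a mapping"])
    known = {"constants", "stimulus", "condition", "solver", "outputs", "seed"}
    for key in sorted(set(document) - known):
        errors.append(f"{key}: unknown key")
    constants = _parse_constants(document.get("constants", {}), errors)
    stimulus = _parse_stimulus(document.get("stimulus", {}), errors)
    condition = _parse_condition(document.get("condition", {}), errors)
    solver = _parse_solver(document.get("solver", {}), errors)
    outputs = document.get("outputs", ".")
    if not isinstance(outputs, str):
        errors.append("outputs: must be a path string")
        outputs = "."
    seed = document.get("seed")
    if seed is not None and (not isinstance(seed, int) or isinstance(seed, bool)):
        errors.append("seed: must be an integer")
        seed = None
    if errors:
        raise ValidationError(errors)
    return RunConfig(
        constants=constants, stimulus=stimulus, condition=condition,
        solver=solver, outputs=outputs, seed=seed,
    )


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML configuration file."""
    text = Path(path).read_text()
    document = yaml.safe_load(text)  # YAML is a superset of JSON
    return parse_config(document)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration so that ``load_config`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
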