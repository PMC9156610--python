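"""Scenario data model and the bundled PRIMAGE endpoint registry.

A :class:`PredictionScenario` carries the summary epidemiology of one
clinical endpoint — outcome proportion, and for time-to-event outcomes the
median time-to-event, median follow-up, prediction time point and expected
study follow-up (all in months) — together with the modelling assumptions
(candidate predictor count, anticipated Nagelkerke R², target shrinkage).
No patient-level data is involved anywhere in the package.

The bundled registry (``data/primage_scenarios.yaml``) holds the eleven
neuroblastoma / high-risk neuroblastoma / DIPG endpoints of the PRIMAGE
case study and uses the same schema users supply via ``--config``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable

import yaml

__all__ = [
    "PredictionScenario",
    "ScenarioValidationError",
    "load_registry",
    "parse_scenarios",
    "scenarios_to_yaml",
]

OUTCOME_KINDS = ("binary", "time_to_event")

#: fields only meaningful for time-to-event scenarios (months)
_TIME_FIELDS = (
    "median_time_to_event",
    "median_follow_up",
    "prediction_timepoint",
    "study_follow_up",
)

DEFAULT_N_PREDICTORS = 30
DEFAULT_R2_NAGELKERKE = 0.3
DEFAULT_SHRINKAGE = 0.9


class ScenarioValidationError(ValueError):
    """A scenario definition violates the schema; names the scenario and field."""

    def __init__(self, scenario_id: str, field_name: str, message: str):
        self.scenario_id = scenario_id
        self.field_name = field_name
        super().__init__(f"scenario {scenario_id!r}, field {field_name!r}: {message}")


@dataclass(frozen=True)
class PredictionScenario:
    """One clinical endpoint with its epidemiological parameters.

    Parameters
    ----------
    id : str
        Short unique label, e.g. ``"nb_mort5y"``.
    tumour : str
        Cohort label (``"NB"``, ``"HR-NB"``, ``"DIPG"`` or free text).
    outcome_kind : str
        ``"binary"`` or ``"time_to_event"``.
    prevalence : float
        Outcome proportion φ in (0, 1): events / N by the prediction
        time point.
    median_time_to_event, median_follow_up : float, optional
        Months; required iff ``outcome_kind == "time_to_event"``.  Feed
        the person-time incidence-rate approximation.
    prediction_timepoint, study_follow_up : float, optional
        Months; required iff time-to-event.  The horizon the model
        predicts risk at, and the expected mean follow-up of subjects in
        the development data.
    n_predictors : int
        Candidate predictor parameters (default 30).
    r2_nagelkerke : float
        Anticipated model fit on the Nagelkerke scale (default 0.3).
    shrinkage_target : float
        Expected shrinkage S of estimated coefficients (default 0.9).
    label : str, optional
        Human-readable name used in rendered tables; defaults to ``id``.
    """

    id: str
    tumour: str
    outcome_kind: str
    prevalence: float
    median_time_to_event: float | None = None
    median_follow_up: float | None = None
    prediction_timepoint: float | None = None
    study_follow_up: float | None = None
    n_predictors: int = DEFAULT_N_PREDICTORS
    r2_nagelkerke: float = DEFAULT_R2_NAGELKERKE
    shrinkage_target: float = DEFAULT_SHRINKAGE
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.id)
        self._validate()

    # -- validation -------------------------------------------------------

    def _fail(self, field_name: str, message: str) -> None:
        raise ScenarioValidationError(self.id or "<unnamed>", field_name, message)

    def _validate(self) -> None:
        if self.outcome_kind not in OUTCOME_KINDS:
            self._fail("outcome_kind", f"must be one of {OUTCOME_KINDS}")
        if not 0.0 < self.prevalence < 1.0:
            self._fail("prevalence", f"must lie in (0, 1), got {self.prevalence}")
        if not (isinstance(self.n_predictors, int) and self.n_predictors >= 1):
            self._fail("n_predictors", f"must be a positive integer, got {self.n_predictors}")
        if not 0.0 < self.r2_nagelkerke < 1.0:
            self._fail("r2_nagelkerke", f"must lie in (0, 1), got {self.r2_nagelkerke}")
        if not 0.0 < self.shrinkage_target < 1.0:
            self._fail("shrinkage_target", f"must lie in (0, 1), got {self.shrinkage_target}")

        if self.outcome_kind == "time_to_event":
            for name in _TIME_FIELDS:
                value = getattr(self, name)
                if value is None:
                    self._fail(name, "required for time-to-event scenarios")
                if not value > 0:
                    self._fail(name, f"must be > 0 months, got {value}")
            # allowed but unusual: median event time at/after median follow-up
            if self.median_time_to_event >= self.median_follow_up:
                warnings.warn(
                    f"scenario {self.id!r}: median_time_to_event "
                    f"({self.median_time_to_event}) is not below median_follow_up "
                    f"({self.median_follow_up})",
                    stacklevel=3,
                )
        else:
            for name in _TIME_FIELDS:
                if getattr(self, name) is not None:
                    self._fail(name, "not allowed on a binary scenario")

    # -- derived ----------------------------------------------------------

    @property
    def is_survival(self) -> bool:
        return self.outcome_kind == "time_to_event"

    def replace(self, **changes: Any) -> "PredictionScenario":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        """Serialise to the config schema (drops unset optional fields)."""
        out: dict[str, Any] = {
            "id": self.id,
            "label": self.label,
            "tumour": self.tumour,
            "outcome_kind": self.outcome_kind,
            "prevalence": self.prevalence,
        }
        for name in _TIME_FIELDS:
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        out["n_predictors"] = self.n_predictors
        out["r2_nagelkerke"] = self.r2_nagelkerke
        out["shrinkage_target"] = self.shrinkage_target
        return out


# ---------------------------------------------------------------------------
# parsing


_KNOWN_FIELDS = {f.name for f in dataclasses.fields(PredictionScenario)}
_REQUIRED_FIELDS = ("id", "tumour", "outcome_kind", "prevalence")


def _scenario_from_mapping(entry: dict[str, Any]) -> PredictionScenario:
    if not isinstance(entry, dict):
        raise ScenarioValidationError("<unnamed>", "<entry>", f"expected a mapping, got {type(entry).__name__}")
    sid = str(entry.get("id", "<unnamed>"))
    for name in _REQUIRED_FIELDS:
        if name not in entry:
            raise ScenarioValidationError(sid, name, "missing required field")
    unknown = set(entry) - _KNOWN_FIELDS
    if unknown:
        raise ScenarioValidationError(sid, sorted(unknown)[0], "unknown field")
    kwargs = dict(entry)
    if "n_predictors" in kwargs:
        n = kwargs["n_predictors"]
        if not (isinstance(n, int) and not isinstance(n, bool)):
            raise ScenarioValidationError(sid, "n_predictors", f"must be an integer, got {n!r}")
    try:
        return PredictionScenario(**kwargs)
    except TypeError as exc:  # wrong types that dataclass construction rejects
        raise ScenarioValidationError(sid, "<entry>", str(exc)) from exc


def parse_scenarios(config: str | Iterable[dict[str, Any]]) -> list[PredictionScenario]:
    """Parse a YAML/JSON document (or an already-parsed list) of scenarios.

    Each entry is validated; unspecified optional fields take the package
    defaults (30 predictors, Nagelkerke R² 0.3, shrinkage 0.9).  An empty
    list parses to an empty collection.

    Raises
    ------
    ScenarioValidationError
        Naming the offending scenario id and field.
    """
    if isinstance(config, str):
        loaded = yaml.safe_load(config)
        if loaded is None:
            loaded = []
    else:
        loaded = list(config)
    if not isinstance(loaded, list):
        raise ScenarioValidationError("<document>", "<root>", "expected a list of scenario mappings")
    scenarios = [_scenario_from_mapping(entry) for entry in loaded]
    seen: set[str] = set()
    for sc in scenarios:
        if sc.id in seen:
            raise ScenarioValidationError(sc.id, "id", "duplicate scenario id")
        seen.add(sc.id)
    return scenarios


def scenarios_to_yaml(scenarios: Iterable[PredictionScenario]) -> str:
    """Serialise scenarios back to the YAML config schema (round-trips)."""
    return yaml.safe_dump(
        [sc.to_dict() for sc in scenarios], sort_keys=False, allow_unicode=True
    )


def load_registry() -> list[PredictionScenario]:
    """Load the bundled registry of the eleven PRIMAGE endpoints.

    Prevalences are stored at the precision reported in the source text
    (e.g. 0.2575 for neuroblastoma relapse/progression), which can be
    finer than the rounded table display.
    """
    text = (
        resources.files("cpmsize").joinpath("data/primage_scenarios.yaml").read_text("utf-8")
    )
    return parse_scenarios(text)
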