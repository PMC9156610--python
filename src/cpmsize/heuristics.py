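"""Events-per-predictor rules of thumb and events-based validation sizes.

The classic rule of thumb for development requires at least 10 outcome
events per candidate predictor parameter (EPP), relaxed to 5 EPP in
later work; both translate to ``n = ceil(EPP·p/φ)``.  They are provided
for comparison only — the multi-criterion development calculation is the
recommended route, and EPP requirements are known to be
context-specific.

For external validation of a fixed model the sizes follow the
events-count consensus: 100 events as a minimum, 200 as desirable, so
``n = ceil(events/φ)``.  For time-to-event endpoints φ is the event
proportion by the prediction horizon, not the person-time rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ValidationSizeResult", "epp_rule_n", "validation_n"]


@dataclass(frozen=True)
class ValidationSizeResult:
    """Minimum (100-event) and desirable (200-event) validation cohort sizes."""

    n_minimum: int
    n_desirable: int
    prevalence: float


def epp_rule_n(events_per_predictor: float, n_predictors: int, prevalence: float) -> int:
    """Sample size under an events-per-predictor rule: ceil(EPP·p/φ).

    Computed independently for each EPP level (the 5-EPP size is not
    derived as half the 10-EPP size).
    """
    if events_per_predictor <= 0:
        raise ValueError(f"events_per_predictor must be > 0, got {events_per_predictor}")
    if n_predictors <= 0:
        raise ValueError(f"n_predictors must be > 0, got {n_predictors}")
    if not 0.0 < prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in (0, 1], got {prevalence}")
    return math.ceil(events_per_predictor * n_predictors / prevalence)


def validation_n(
    prevalence: float,
    minimum_events: int = 100,
    desirable_events: int = 200,
) -> ValidationSizeResult:
    """Validation cohort sizes from required events counts: ceil(events/φ)."""
    if not 0.0 < prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in (0, 1], got {prevalence}")
    if minimum_events <= 0 or desirable_events <= 0:
        raise ValueError("events counts must be positive")
    if desirable_events < minimum_events:
        raise ValueError("desirable_events must be >= minimum_events")
    return ValidationSizeResult(
        n_minimum=math.ceil(minimum_events / prevalence),
        n_desirable=math.ceil(desirable_events / prevalence),
        prevalence=prevalence,
    )
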