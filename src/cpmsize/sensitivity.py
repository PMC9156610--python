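"""Sensitivity sweeps: predictor count, anticipated fit, follow-up ratio.

Three one-parameter sweeps quantify how the development sample size
responds to the planning assumptions, all else held fixed:

* predictor count over 5–30 in steps of 5 (the shrinkage and optimism
  criteria are exactly proportional to the predictor count before
  ceiling, so halving the predictors roughly halves n whenever they
  dominate);
* anticipated Nagelkerke R² over {0.15, 0.3, 0.5, 0.8} (n falls as the
  anticipated fit rises);
* for time-to-event scenarios, the ratio of expected mean follow-up to
  the prediction time point over 1–4 (longer follow-up accrues more
  events per subject, lowering n, with diminishing returns).

Sweeps never mutate the input scenario; each grid point is evaluated on
a validated copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .development import DevelopmentSizeResult, develop_scenario, develop_survival
from .effect_size import person_time_rate
from .scenarios import PredictionScenario

__all__ = [
    "SweepResult",
    "sweep_predictors",
    "sweep_r2",
    "sweep_followup_ratio",
    "DEFAULT_PREDICTOR_GRID",
    "DEFAULT_R2_GRID",
    "DEFAULT_RATIO_GRID",
]

DEFAULT_PREDICTOR_GRID: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
DEFAULT_R2_GRID: tuple[float, ...] = (0.15, 0.3, 0.5, 0.8)
DEFAULT_RATIO_GRID: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class SweepResult:
    """A parameter grid with the final sample size and EPP at each point."""

    scenario_id: str
    swept_parameter: str
    grid: tuple[float, ...]
    final_n: tuple[int, ...]
    epp: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.final_n) == len(self.epp)):
            raise ValueError("grid, final_n and epp must share length")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid must be strictly increasing")

    def value_at(self, grid_point: float) -> int:
        """Final sample size at one grid point (exact match required)."""
        try:
            return self.final_n[self.grid.index(grid_point)]
        except ValueError:
            raise KeyError(f"grid point {grid_point} not in sweep grid {self.grid}") from None

    def to_records(self) -> list[dict[str, object]]:
        """Long-format rows (scenario_id, parameter, value, final_n, epp)."""
        return [
            {
                "scenario_id": self.scenario_id,
                "parameter": self.swept_parameter,
                "value": g,
                "final_n": n,
                "epp": e,
            }
            for g, n, e in zip(self.grid, self.final_n, self.epp)
        ]


def _collect(
    scenario_id: str, parameter: str, grid: Sequence[float], results: Sequence[DevelopmentSizeResult]
) -> SweepResult:
    return SweepResult(
        scenario_id=scenario_id,
        swept_parameter=parameter,
        grid=tuple(grid),
        final_n=tuple(r.final_n for r in results),
        epp=tuple(r.epp for r in results),
    )


def sweep_predictors(
    scenario: PredictionScenario,
    grid: Sequence[int] = DEFAULT_PREDICTOR_GRID,
) -> SweepResult:
    """Development size as the candidate predictor count varies."""
    results = [develop_scenario(scenario.replace(n_predictors=int(p))) for p in grid]
    return _collect(scenario.id, "n_predictors", [float(p) for p in grid], results)


def sweep_r2(
    scenario: PredictionScenario,
    grid: Sequence[float] = DEFAULT_R2_GRID,
) -> SweepResult:
    """Development size as the anticipated Nagelkerke R² varies."""
    results = [develop_scenario(scenario.replace(r2_nagelkerke=float(r))) for r in grid]
    return _collect(scenario.id, "r2_nagelkerke", grid, results)


def sweep_followup_ratio(
    scenario: PredictionScenario,
    grid: Sequence[float] = DEFAULT_RATIO_GRID,
    *,
    rescale_rate: bool = False,
) -> SweepResult:
    """Development size as mean follow-up varies relative to the horizon.

    At ratio r the expected mean follow-up entering the survival criteria
    is set to r × prediction_timepoint.  By default the person-time rate
    stays at the value implied by the scenario's own epidemiology (the
    disease does not change because the study observes longer); with
    ``rescale_rate=True`` the rate is also recomputed with the median
    follow-up set to r × prediction_timepoint, coupling both follow-up
    quantities to the ratio.
    """
    if not scenario.is_survival:
        raise ValueError(
            f"scenario {scenario.id!r} is binary; the follow-up ratio sweep "
            "applies to time-to-event scenarios only"
        )
    base_rate = person_time_rate(
        scenario.prevalence,
        scenario.median_time_to_event,
        scenario.median_follow_up,
    ).rate
    results = []
    for ratio in grid:
        mean_fu = float(ratio) * scenario.prediction_timepoint
        if rescale_rate:
            rate = person_time_rate(
                scenario.prevalence, scenario.median_time_to_event, mean_fu
            ).rate
        else:
            rate = base_rate
        results.append(
            develop_survival(
                scenario.n_predictors,
                rate,
                scenario.prediction_timepoint,
                mean_fu,
                r2_nagelkerke=scenario.r2_nagelkerke,
                shrinkage_target=scenario.shrinkage_target,
            )
        )
    return _collect(scenario.id, "followup_ratio", grid, results)
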