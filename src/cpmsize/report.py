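"""Assemble the summary tables for a set of scenarios.

Four tables mirror the case-study presentation: person-time rates for
the time-to-event endpoints, development sizes per method (multi-
criterion, 10-EPP, 5-EPP) with the implied EPP, a Nagelkerke-R²
sensitivity table, and validation cohort sizes.  Output is fully
deterministic: the same scenarios yield byte-identical CSV/JSON.
Rendering precision is fixed — rates at 4 decimals, EPP at 2, sizes as
integers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .development import develop_scenario
from .effect_size import person_time_rate
from .heuristics import epp_rule_n, validation_n
from .scenarios import PredictionScenario
from .sensitivity import DEFAULT_R2_GRID, sweep_r2

__all__ = ["ReportBundle", "run_report"]

logger = logging.getLogger("cpmsize")


@dataclass
class ReportBundle:
    """The four scenario tables plus run metadata and per-scenario errors."""

    rates_table: pd.DataFrame
    development_table: pd.DataFrame
    r2_sensitivity_table: pd.DataFrame
    validation_table: pd.DataFrame
    metadata: dict
    errors: dict[str, str] = dc_field(default_factory=dict)

    _TABLES = ("rates_table", "development_table", "r2_sensitivity_table", "validation_table")

    def write_csv(self, out_dir: str | Path) -> list[Path]:
        """Write one CSV per table into ``out_dir``; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in self._TABLES:
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False, lineterminator="\n")
            paths.append(path)
        return paths

    def to_json(self) -> str:
        """Serialise all tables and metadata to a single JSON document."""
        payload = {
            name: getattr(self, name).to_dict(orient="records") for name in self._TABLES
        }
        payload["metadata"] = self.metadata
        payload["errors"] = self.errors
        return json.dumps(payload, indent=2, sort_keys=False)

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json() + "\n", encoding="utf-8")
        return path


def _fmt_rate(rate: float) -> float:
    return round(rate, 4)


def run_report(
    scenarios: Sequence[PredictionScenario],
    *,
    r2_grid: Sequence[float] = DEFAULT_R2_GRID,
    include_timestamp: bool = False,
) -> ReportBundle:
    """Compute every table for ``scenarios``.

    Per-scenario computation errors are collected under the scenario id
    rather than aborting the whole report.  ``include_timestamp`` adds a
    wall-clock stamp to the metadata (off by default so repeated runs are
    byte-identical).
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("no scenarios")

    from . import __version__

    rates_rows, dev_rows, r2_rows, val_rows = [], [], [], []
    errors: dict[str, str] = {}
    for sc in scenarios:
        try:
            if sc.is_survival:
                rates_rows.append(
                    {
                        "model": sc.label,
                        "prevalence": sc.prevalence,
                        "median_time_to_event": sc.median_time_to_event,
                        "median_follow_up": sc.median_follow_up,
                        "rate": _fmt_rate(
                            person_time_rate(
                                sc.prevalence, sc.median_time_to_event, sc.median_follow_up
                            ).rate
                        ),
                        "prediction_timepoint": sc.prediction_timepoint,
                        "study_follow_up": sc.study_follow_up,
                    }
                )
            dev = develop_scenario(sc)
            dev_rows.append(
                {
                    "model": sc.label,
                    "development_n": dev.final_n,
                    "epp10_n": epp_rule_n(10, sc.n_predictors, sc.prevalence),
                    "epp5_n": epp_rule_n(5, sc.n_predictors, sc.prevalence),
                    "implied_epp": dev.epp,
                }
            )
            for rec in sweep_r2(sc, r2_grid).to_records():
                r2_rows.append(
                    {
                        "model": sc.label,
                        "r2_nagelkerke": rec["value"],
                        "final_n": rec["final_n"],
                        "epp": rec["epp"],
                    }
                )
            val = validation_n(sc.prevalence)
            val_rows.append(
                {
                    "model": sc.label,
                    "n_minimum_100_events": val.n_minimum,
                    "n_desirable_200_events": val.n_desirable,
                }
            )
        except (ValueError, ArithmeticError) as exc:
            logger.warning("scenario %s failed: %s", sc.id, exc)
            errors[sc.id] = str(exc)

    metadata = {
        "package": "cpmsize",
        "version": __version__,
        "defaults": {
            "n_predictors": 30,
            "r2_nagelkerke": 0.3,
            "shrinkage_target": 0.9,
            "optimism_margin": 0.05,
            "risk_margin": 0.05,
        },
        "r2_grid": [float(r) for r in r2_grid],
        "n_scenarios": len(scenarios),
    }
    if include_timestamp:
        import datetime

        metadata["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()

    return ReportBundle(
        rates_table=pd.DataFrame(
            rates_rows,
            columns=[
                "model",
                "prevalence",
                "median_time_to_event",
                "median_follow_up",
                "rate",
                "prediction_timepoint",
                "study_follow_up",
            ],
        ),
        development_table=pd.DataFrame(
            dev_rows, columns=["model", "development_n", "epp10_n", "epp5_n", "implied_epp"]
        ),
        r2_sensitivity_table=pd.DataFrame(
            r2_rows, columns=["model", "r2_nagelkerke", "final_n", "epp"]
        ),
        validation_table=pd.DataFrame(
            val_rows, columns=["model", "n_minimum_100_events", "n_desirable_200_events"]
        ),
        metadata=metadata,
        errors=errors,
    )
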