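"""Multi-criterion minimum sample size for model development.

Three criteria are evaluated and the largest resulting n is taken:

1. *shrinkage* — enough data that the expected (heuristic) shrinkage of
   the fitted coefficients is at least the target S (default 0.9):

       n = p / ((S − 1) · ln(1 − R²_CS / S))

   with p candidate predictor parameters and R²_CS the anticipated
   Cox–Snell fit.
2. *optimism* — a small absolute difference δ (default 0.05) between the
   apparent and optimism-adjusted Nagelkerke R²; the same formula with S
   replaced by S₂ = R²_CS / (R²_CS + δ·max R²_CS).
3. *risk_precision* — a precise estimate of the overall outcome risk.
   Binary: n = (z₀.₉₇₅ / m)² · φ(1 − φ) with margin m (default 0.05).
   Time-to-event: the smallest n whose 95% interval for the cumulative
   risk F(t*) = 1 − exp(−rate·t*), obtained by transforming the
   multiplicative (log-scale) interval rate·exp(±1.96/√E) with
   E = n·rate·mean-follow-up expected events, has half-width ≤ m.

Each criterion is solved in the reals and ceilinged to an integer; the
final n is the maximum of the ceilinged values.  Expected events are
n·φ (binary) or n·rate·mean-follow-up (time-to-event) and give the
implied events-per-predictor (EPP) of the chosen size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .effect_size import (
    EffectSizeSpec,
    max_r2_cs_binary,
    max_r2_cs_survival,
    nagelkerke_to_cox_snell,
    person_time_rate,
)
from .scenarios import PredictionScenario

__all__ = [
    "DevelopmentSizeResult",
    "develop_binary",
    "develop_survival",
    "develop_scenario",
    "epp_from_n",
]

Z_975 = 1.96  # fixed two-sided 95% normal quantile, by convention
DEFAULT_OPTIMISM_MARGIN = 0.05
DEFAULT_RISK_MARGIN = 0.05


@dataclass(frozen=True)
class DevelopmentSizeResult:
    """Per-criterion sample sizes and the derived quantities of the chosen n."""

    criterion_sizes: dict[str, int]
    final_n: int
    expected_events: float
    epp: float
    effect: EffectSizeSpec
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def dominating_criterion(self) -> str:
        return max(self.criterion_sizes, key=self.criterion_sizes.__getitem__)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 → 0.13 at 2 dp), for reported EPP."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def epp_from_n(n: int, prevalence: float, n_predictors: int) -> float:
    """Events per predictor implied by a sample size: n·φ/p, half-up to 2 dp."""
    if n <= 0 or n_predictors <= 0 or prevalence <= 0:
        raise ValueError("n, prevalence and n_predictors must all be positive")
    return _round_half_up(n * prevalence / n_predictors)


def _shrinkage_n(n_predictors: int, r2_cs: float, s: float) -> int:
    """Real-valued solution of the shrinkage equation, ceilinged."""
    return math.ceil(n_predictors / ((s - 1.0) * math.log(1.0 - r2_cs / s)))


def _check_effect(effect: EffectSizeSpec, shrinkage_target: float) -> None:
    if not 0.0 < shrinkage_target < 1.0:
        raise ValueError(f"shrinkage_target must lie in (0, 1), got {shrinkage_target}")
    if effect.r2_cs <= 0.0:
        raise ValueError(f"r2_cs must be > 0, got {effect.r2_cs}")
    if effect.r2_cs >= shrinkage_target:
        raise ValueError(
            "shrinkage criterion unsatisfiable: anticipated Cox-Snell R2 "
            f"({effect.r2_cs:.4g}) must be below the shrinkage target "
            f"({shrinkage_target})"
        )


def _shrinkage_and_optimism(
    n_predictors: int,
    effect: EffectSizeSpec,
    shrinkage_target: float,
    optimism_margin: float,
) -> tuple[int, int]:
    n_shrink = _shrinkage_n(n_predictors, effect.r2_cs, shrinkage_target)
    s2 = effect.r2_cs / (effect.r2_cs + optimism_margin * effect.max_r2_cs)
    n_optimism = _shrinkage_n(n_predictors, effect.r2_cs, s2)
    return n_shrink, n_optimism


def develop_binary(
    n_predictors: int,
    prevalence: float,
    effect: EffectSizeSpec | None = None,
    *,
    r2_nagelkerke: float = 0.3,
    shrinkage_target: float = 0.9,
    optimism_margin: float = DEFAULT_OPTIMISM_MARGIN,
    risk_margin: float = DEFAULT_RISK_MARGIN,
) -> DevelopmentSizeResult:
    """Minimum development sample size for a binary-outcome model.

    When ``effect`` is not supplied it is derived from ``r2_nagelkerke``
    and the prevalence-dependent Cox–Snell ceiling.
    """
    if n_predictors < 1:
        raise ValueError(f"n_predictors must be >= 1, got {n_predictors}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    if effect is None:
        effect = nagelkerke_to_cox_snell(r2_nagelkerke, max_r2_cs_binary(prevalence))
    _check_effect(effect, shrinkage_target)

    n_shrink, n_optimism = _shrinkage_and_optimism(
        n_predictors, effect, shrinkage_target, optimism_margin
    )
    phi = prevalence
    n_risk = math.ceil((Z_975 / risk_margin) ** 2 * phi * (1.0 - phi))

    sizes = {"shrinkage": n_shrink, "optimism": n_optimism, "risk_precision": n_risk}
    final_n = max(sizes.values())
    events = final_n * phi
    return DevelopmentSizeResult(
        criterion_sizes=sizes,
        final_n=final_n,
        expected_events=events,
        epp=_round_half_up(events / n_predictors),
        effect=effect,
    )


def _survival_risk_half_width(
    n: int, rate: float, timepoint: float, mean_follow_up: float
) -> float:
    """Half-width of the 95% interval for F(t*) at sample size n."""
    events = n * rate * mean_follow_up
    # cap the log-scale spread so exp() cannot overflow; the upper risk
    # bound saturates at 1 long before the cap matters
    spread = min(Z_975 / math.sqrt(events), 700.0)
    upper = 1.0 - math.exp(-min(rate * math.exp(spread) * timepoint, 700.0))
    lower = 1.0 - math.exp(-rate * math.exp(-spread) * timepoint)
    return (upper - lower) / 2.0


def _survival_risk_precision_n(
    rate: float, timepoint: float, mean_follow_up: float, risk_margin: float
) -> int:
    """Smallest integer n meeting the cumulative-risk precision margin.

    The half-width is monotone decreasing in n, so bracket by doubling
    and close in with bisection over integers.
    """
    if _survival_risk_half_width(1, rate, timepoint, mean_follow_up) <= risk_margin:
        return 1
    hi = 2
    while _survival_risk_half_width(hi, rate, timepoint, mean_follow_up) > risk_margin:
        hi *= 2
        if hi > 10**9:
            raise ValueError(
                f"risk_margin {risk_margin} unattainable below n = 1e9; "
                "check rate and follow-up"
            )
    lo = hi // 2  # half-width(lo) > margin, half-width(hi) <= margin
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _survival_risk_half_width(mid, rate, timepoint, mean_follow_up) <= risk_margin:
            hi = mid
        else:
            lo = mid
    return hi


def develop_survival(
    n_predictors: int,
    rate: float,
    prediction_timepoint: float,
    mean_follow_up: float,
    effect: EffectSizeSpec | None = None,
    *,
    r2_nagelkerke: float = 0.3,
    shrinkage_target: float = 0.9,
    optimism_margin: float = DEFAULT_OPTIMISM_MARGIN,
    risk_margin: float = DEFAULT_RISK_MARGIN,
) -> DevelopmentSizeResult:
    """Minimum development sample size for a time-to-event model.

    ``rate`` is the person-time incidence rate (events per person-month),
    typically from :func:`cpmsize.effect_size.person_time_rate`;
    ``prediction_timepoint`` is the horizon t* the model predicts risk at
    and ``mean_follow_up`` the expected average follow-up per subject in
    the development data (both months).
    """
    if n_predictors < 1:
        raise ValueError(f"n_predictors must be >= 1, got {n_predictors}")
    if rate <= 0 or prediction_timepoint <= 0 or mean_follow_up <= 0:
        raise ValueError("rate, prediction_timepoint and mean_follow_up must be > 0")
    if effect is None:
        effect = nagelkerke_to_cox_snell(
            r2_nagelkerke, max_r2_cs_survival(rate, mean_follow_up)
        )
    _check_effect(effect, shrinkage_target)

    n_shrink, n_optimism = _shrinkage_and_optimism(
        n_predictors, effect, shrinkage_target, optimism_margin
    )
    n_risk = _survival_risk_precision_n(
        rate, prediction_timepoint, mean_follow_up, risk_margin
    )

    sizes = {"shrinkage": n_shrink, "optimism": n_optimism, "risk_precision": n_risk}
    final_n = max(sizes.values())
    events = final_n * rate * mean_follow_up
    notes: tuple[str, ...] = ()
    if events < 1.0:
        notes = (
            f"fewer than one expected event (E = {events:.3g}) at the final "
            "sample size; inputs are outside the method's intended range",
        )
    return DevelopmentSizeResult(
        criterion_sizes=sizes,
        final_n=final_n,
        expected_events=events,
        epp=_round_half_up(events / n_predictors),
        effect=effect,
        warnings=notes,
    )


def develop_scenario(
    scenario: PredictionScenario,
    *,
    optimism_margin: float = DEFAULT_OPTIMISM_MARGIN,
    risk_margin: float = DEFAULT_RISK_MARGIN,
    round_rate_dp: int | None = None,
) -> DevelopmentSizeResult:
    """Development sample size for a scenario, dispatching on outcome kind.

    For time-to-event scenarios the person-time rate is derived from the
    scenario's summary epidemiology at full precision; ``round_rate_dp``
    instead rounds it first (e.g. 4 to mimic working from a printed
    4-decimal rate).
    """
    if not scenario.is_survival:
        return develop_binary(
            scenario.n_predictors,
            scenario.prevalence,
            r2_nagelkerke=scenario.r2_nagelkerke,
            shrinkage_target=scenario.shrinkage_target,
            optimism_margin=optimism_margin,
            risk_margin=risk_margin,
        )
    rate = person_time_rate(
        scenario.prevalence,
        scenario.median_time_to_event,
        scenario.median_follow_up,
    ).rate
    if round_rate_dp is not None:
        rate = round(rate, round_rate_dp)
    return develop_survival(
        scenario.n_predictors,
        rate,
        scenario.prediction_timepoint,
        scenario.study_follow_up,
        r2_nagelkerke=scenario.r2_nagelkerke,
        shrinkage_target=scenario.shrinkage_target,
        optimism_margin=optimism_margin,
        risk_margin=risk_margin,
    )
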