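"""Pseudo-R² conversions and the person-time incidence-rate approximation.

The anticipated model fit is specified on the Nagelkerke scale, which
rescales the likelihood-based Cox–Snell R² by its outcome-dependent
maximum so it spans (0, 1):

    R²_Nagelkerke = R²_CS / max(R²_CS)

For a binary outcome with proportion φ the ceiling is set by the null
(intercept-only) Bernoulli log-likelihood,

    max(R²_CS) = 1 − exp(2·(φ ln φ + (1 − φ) ln(1 − φ))),

and for a time-to-event outcome by the null exponential/Poisson
log-likelihood with e expected events per subject,

    max(R²_CS) = 1 − exp(2·e·(ln e − 1)),     e = rate × mean follow-up.

The person-time incidence rate needed for survival planning is rarely
published directly; it is approximated from summary quantities by
assuming every event contributes the median time-to-event of person-time
and every non-event the median follow-up:

    rate = p / (p·t_event + (1 − p)·t_follow-up),

with p the outcome proportion.  When only a prevalence at a fixed time
point is available, that time point may be passed as the follow-up time,
as if all non-events were censored there (the caller's choice).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "EffectSizeSpec",
    "PersonTimeRate",
    "max_r2_cs_binary",
    "max_r2_cs_survival",
    "nagelkerke_to_cox_snell",
    "cox_snell_to_nagelkerke",
    "person_time_rate",
]


@dataclass(frozen=True)
class EffectSizeSpec:
    """Anticipated model fit: Nagelkerke R², the Cox–Snell ceiling, and
    the implied Cox–Snell R² (= product of the other two)."""

    r2_nagelkerke: float
    max_r2_cs: float
    r2_cs: float

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_nagelkerke < 1.0:
            raise ValueError(f"r2_nagelkerke must lie in (0, 1), got {self.r2_nagelkerke}")
        if not 0.0 < self.max_r2_cs < 1.0:
            raise ValueError(f"max_r2_cs must lie in (0, 1), got {self.max_r2_cs}")
        expected = self.r2_nagelkerke * self.max_r2_cs
        if not math.isclose(self.r2_cs, expected, rel_tol=1e-12):
            raise ValueError(
                f"inconsistent spec: r2_cs={self.r2_cs} != "
                f"r2_nagelkerke*max_r2_cs={expected}"
            )


@dataclass(frozen=True)
class PersonTimeRate:
    """Approximate incidence rate (events per person-month) with the
    summary inputs it was derived from echoed back."""

    rate: float
    prevalence: float
    median_time_to_event: float
    median_follow_up: float


def max_r2_cs_binary(prevalence: float) -> float:
    """Maximum attainable Cox–Snell R² for a binary outcome.

    ``1 − exp(2·(φ ln φ + (1−φ) ln(1−φ)))`` — the ceiling imposed by the
    null-model Bernoulli likelihood.  Symmetric in φ ↔ 1−φ; equals 0.75
    at φ = 0.5 and tends to 0 as φ approaches either boundary.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {prevalence}")
    phi = prevalence
    lnl_null = phi * math.log(phi) + (1.0 - phi) * math.log(1.0 - phi)
    return 1.0 - math.exp(2.0 * lnl_null)


def max_r2_cs_survival(rate: float, mean_follow_up: float) -> float:
    """Maximum attainable Cox–Snell R² for a time-to-event outcome.

    With ``e = rate × mean_follow_up`` expected events per subject, the
    per-subject null exponential log-likelihood is ``e·(ln e − 1)``,
    giving ``1 − exp(2·e·(ln e − 1))``.  Warns when e ≥ 1 (more than one
    expected event per subject is outside the intended planning range).
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if mean_follow_up <= 0:
        raise ValueError(f"mean_follow_up must be > 0, got {mean_follow_up}")
    e = rate * mean_follow_up
    if e >= 1.0:
        warnings.warn(
            f"expected events per subject e = {e:.3g} >= 1; "
            "the planning approximation is intended for e < 1",
            stacklevel=2,
        )
    return 1.0 - math.exp(2.0 * e * (math.log(e) - 1.0))


def nagelkerke_to_cox_snell(r2_nagelkerke: float, max_r2_cs: float) -> EffectSizeSpec:
    """Convert an anticipated Nagelkerke R² to the Cox–Snell scale.

    ``R²_CS = R²_Nagelkerke × max(R²_CS)``; all three quantities are
    returned together as an :class:`EffectSizeSpec`.
    """
    if not 0.0 < r2_nagelkerke < 1.0:
        raise ValueError(f"r2_nagelkerke must lie in (0, 1), got {r2_nagelkerke}")
    if not 0.0 < max_r2_cs < 1.0:
        raise ValueError(f"max_r2_cs must lie in (0, 1), got {max_r2_cs}")
    return EffectSizeSpec(
        r2_nagelkerke=r2_nagelkerke,
        max_r2_cs=max_r2_cs,
        r2_cs=r2_nagelkerke * max_r2_cs,
    )


def cox_snell_to_nagelkerke(r2_cs: float, max_r2_cs: float) -> float:
    """Inverse conversion: ``R²_Nagelkerke = R²_CS / max(R²_CS)``."""
    if not 0.0 < max_r2_cs < 1.0:
        raise ValueError(f"max_r2_cs must lie in (0, 1), got {max_r2_cs}")
    if not 0.0 < r2_cs < max_r2_cs:
        raise ValueError(f"r2_cs must lie in (0, max_r2_cs={max_r2_cs}), got {r2_cs}")
    return r2_cs / max_r2_cs


def person_time_rate(
    prevalence: float,
    median_time_to_event: float,
    median_follow_up: float,
) -> PersonTimeRate:
    """Approximate the person-time incidence rate from summary data.

    ``rate = p / (p·t_event + (1−p)·t_follow-up)`` — the cohort identity
    in which each of the E = p·N events contributes the median
    time-to-event of person-time and each of the N − E non-events the
    median follow-up.  Returned at full precision; round only for
    display.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    if median_time_to_event <= 0:
        raise ValueError(f"median_time_to_event must be > 0, got {median_time_to_event}")
    if median_follow_up <= 0:
        raise ValueError(f"median_follow_up must be > 0, got {median_follow_up}")
    p = prevalence
    rate = p / (p * median_time_to_event + (1.0 - p) * median_follow_up)
    return PersonTimeRate(
        rate=rate,
        prevalence=p,
        median_time_to_event=median_time_to_event,
        median_follow_up=median_follow_up,
    )
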