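"""Independent oracles for the development-size criteria.

These deliberately avoid the closed-form solutions used by the package:
each criterion is restated as "the smallest integer n satisfying the
criterion's defining inequality", with the expected shrinkage at a given
n obtained by solving its fixed-point equation numerically (brentq) and
the smallest n found by integer scan.  Agreement between these solvers
and the package's closed forms is a genuine two-route check.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

Z = 1.96


def expected_shrinkage(n: int, n_predictors: int, r2_cs: float) -> float:
    """Heuristic expected shrinkage at sample size n.

    Solves s = 1 + p / (n * ln(1 - r2_cs / s)) for s in (r2_cs, 1).
    """

    def f(s: float) -> float:
        return s - (1.0 + n_predictors / (n * math.log(1.0 - r2_cs / s)))

    lo = r2_cs * (1.0 + 1e-10)
    hi = 1.0 - 1e-12
    if f(lo) > 0.0:
        # n too small for any shrinkage level above r2_cs to be expected
        return 0.0
    return brentq(f, lo, hi, xtol=1e-13)


def smallest_n(predicate, start: int = 1, limit: int = 10**6) -> int:
    """Smallest integer n >= start with predicate(n) true (monotone scan)."""
    n = start
    while n <= limit:
        if predicate(n):
            return n
        n += 1
    raise RuntimeError(f"no n <= {limit} satisfies the criterion")


def oracle_shrinkage_n(n_predictors: int, r2_cs: float, target: float) -> int:
    return smallest_n(lambda n: expected_shrinkage(n, n_predictors, r2_cs) >= target)


def oracle_optimism_n(
    n_predictors: int, r2_cs: float, max_r2_cs: float, margin: float
) -> int:
    def ok(n: int) -> bool:
        s = expected_shrinkage(n, n_predictors, r2_cs)
        if s <= 0.0:
            return False
        return r2_cs * (1.0 - s) / s <= margin * max_r2_cs

    return smallest_n(ok)


def oracle_risk_n_binary(prevalence: float, margin: float) -> int:
    return smallest_n(
        lambda n: Z * math.sqrt(prevalence * (1.0 - prevalence) / n) <= margin
    )


def oracle_risk_n_survival(
    rate: float, timepoint: float, mean_follow_up: float, margin: float
) -> int:
    def ok(n: int) -> bool:
        events = n * rate * mean_follow_up
        spread = Z / math.sqrt(events)
        upper = 1.0 - math.exp(-rate * math.exp(spread) * timepoint)
        lower = 1.0 - math.exp(-rate * math.exp(-spread) * timepoint)
        return (upper - lower) / 2.0 <= margin

    return smallest_n(ok)


def oracle_final_n_survival(
    n_predictors: int,
    rate: float,
    timepoint: float,
    mean_follow_up: float,
    r2_nagelkerke: float = 0.3,
    shrinkage_target: float = 0.9,
    optimism_margin: float = 0.05,
    risk_margin: float = 0.05,
) -> int:
    e = rate * mean_follow_up
    max_r2 = 1.0 - math.exp(2.0 * e * (math.log(e) - 1.0))
    r2_cs = r2_nagelkerke * max_r2
    return max(
        oracle_shrinkage_n(n_predictors, r2_cs, shrinkage_target),
        oracle_optimism_n(n_predictors, r2_cs, max_r2, optimism_margin),
        oracle_risk_n_survival(rate, timepoint, mean_follow_up, risk_margin),
    )


def oracle_final_n_binary(
    n_predictors: int,
    prevalence: float,
    r2_nagelkerke: float = 0.3,
    shrinkage_target: float = 0.9,
    optimism_margin: float = 0.05,
    risk_margin: float = 0.05,
) -> int:
    phi = prevalence
    max_r2 = 1.0 - math.exp(
        2.0 * (phi * math.log(phi) + (1.0 - phi) * math.log(1.0 - phi))
    )
    r2_cs = r2_nagelkerke * max_r2
    return max(
        oracle_shrinkage_n(n_predictors, r2_cs, shrinkage_target),
        oracle_optimism_n(n_predictors, r2_cs, max_r2, optimism_margin),
        oracle_risk_n_binary(phi, risk_margin),
    )
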