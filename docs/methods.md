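# Methods

## Problem and scope

`cpmsize` answers a planning question: how many subjects are needed to
*develop* a multivariable clinical prediction model (logistic for binary
outcomes, proportional-hazards-type for time-to-event outcomes) so that it is
unlikely to be badly overfitted, and how many to *validate* a fixed model
reproducibly. Inputs are summary epidemiology only — an outcome proportion,
and for survival endpoints two median times and a follow-up expectation — so
the package fits the design phase of a study, before any data exist. It does
not fit models, estimate R² from data, or handle continuous outcomes.

## Development criteria

Three criteria are computed and the largest ceilinged n is returned, along
with the per-criterion breakdown so the user can see what drives the answer.

1. **Shrinkage.** The heuristic expected shrinkage of maximum-likelihood
   coefficients satisfies `s = 1 + p/(n·ln(1 − R²_CS/s))`; requiring `s ≥ S`
   and solving at equality gives `n = p/((S−1)·ln(1 − R²_CS/S))`. Default
   target `S = 0.9` (≤ 10% expected attenuation).
2. **Optimism.** The optimism of the apparent fit, `R²_CS(1−s)/s`, is capped
   at `δ·max(R²_CS)` (δ = 0.05 on the Nagelkerke scale), which is the
   shrinkage formula evaluated at `S₂ = R²_CS/(R²_CS + δ·max R²_CS)`.
3. **Risk precision.** The overall outcome risk must be estimable with 95%
   half-width ≤ m = 0.05. Binary outcomes use the normal-approximation
   binomial interval, giving `n = (z/m)²·φ(1−φ)` with z fixed at 1.96 (the
   conventional quantile, not recomputed). Survival outcomes transform the
   multiplicative rate interval `λ·exp(±z/√E)` through
   `F(t*) = 1 − exp(−λt*)`; the half-width is monotone decreasing in n, and
   the smallest integer n is found by doubling then integer bisection. The
   log-scale spread is capped at 700 so the exponential cannot overflow for
   pathological inputs (the risk bound saturates at 1 long before the cap
   binds).

Each criterion is solved in the reals and ceilinged *per criterion*; the
final n is the maximum of the ceilinged values. This ordering reproduces the
case-study integers exactly (e.g. 1043 and 2247 for the balanced binary
endpoint) where ceiling-after-max would not be guaranteed to.

Anticipated fit enters on the Nagelkerke scale (default 0.3 — a compromise
between 0.15, suggested when nothing is known about the predictors, and 0.5,
suggested when direct measures of the outcome process are included) and is
converted by `R²_CS = R²_N · max(R²_CS)`. The binary ceiling comes from the
null Bernoulli likelihood; the survival ceiling from the null
exponential/Poisson likelihood with `e = λ ×` mean follow-up expected events
per subject, `max(R²_CS) = 1 − exp(2e(ln e − 1))`. The survival ceiling is
the form used by the reference implementation of the methodology; it is
validated in the test suite against an independent numerical solver (see
below).

**Validity range.** The survival ceiling increases in `e` only up to `e = 1`
(one expected event per subject) and contracts beyond it, so required sample
sizes are not monotone in follow-up once `e > 1`. The package warns when
`e ≥ 1`; planning inputs should normally keep the expectation below one
event per subject.

## Person-time rate approximation

`λ = p/(p·t_event + (1−p)·t_follow-up)` treats the cohort as E = pN events
each contributing the median time-to-event and N−E non-events each
contributing the median follow-up. It is exact for that stylised cohort, and
an approximation for real data in which event and censoring times are
dispersed around their medians. When no follow-up estimate exists, the time
point at which the prevalence was measured may be passed as the follow-up
(all non-events censored there) — this is left to the caller rather than
automated, since it changes the meaning of the input. Rates are carried at
full precision; the 4-decimal rendering is display-only, and
`develop_scenario(..., round_rate_dp=4)` exists to mimic a calculation
started from a printed 4-dp rate (the two modes differ by well under 1% in
final n for the bundled scenarios).

## Rules of thumb and validation sizes

`epp_rule_n` implements `ceil(EPP·p/φ)` independently for each EPP level;
the 5-EPP size is *not* derived as half the 10-EPP size, because the
independent form is the rule's definition (the two differ by at most one
count through the ceiling). For time-to-event endpoints the rules use the
event proportion by the horizon, not the person-time rate, matching how the
rules are applied in practice. Validation sizes are `ceil(events/φ)` with
100 (minimum) and 200 (desirable) events.

## Sensitivity sweeps

Sweeps copy the scenario per grid point (never mutating the input) and rerun
the full criterion set. Defaults mirror the case study: predictors 5–30 by
5, Nagelkerke R² {0.15, 0.3, 0.5, 0.8}, follow-up/horizon ratio 1–4.

For the ratio sweep the mean follow-up entering the survival criteria is set
to ratio × prediction time point while the person-time rate stays at the
scenario's epidemiological value: observing a cohort longer changes the
person-time accrued in the development data, not the disease's incidence.
The alternative reading — rescaling the median follow-up inside the rate
approximation as well — is available via `rescale_rate=True`; it couples the
two follow-up quantities and yields much flatter curves (the two effects
partially cancel), and the default was chosen because the uncoupled reading
reproduces the 13.8–23% ratio-1→2 reductions reported for the case-study
endpoints. Note the `e > 1` caveat above: the HR-NB relapse endpoint crosses
`e = 1` near ratio 3, beyond which its required n rises again slightly.

## Registry and reproducibility

The eleven bundled endpoints are data, not code (`data/primage_scenarios.yaml`,
same schema as user configs). Prevalences are stored at the precision of the
source text (0.2575, not the display rounding 0.258), because several derived
integers (e.g. the 10-EPP size 1166) are reproducible only from the full
value. Everything in the package is deterministic: identical inputs give
byte-identical CSV/JSON reports.

Known divergences from the published case-study tables are deliberate and
asserted in the test suite: the published NB binary sizes (1111, 2383) sit
~0.2–0.3% below the closed-form values (1114, 2387); the published DIPG
1-year binary rows duplicate the φ=0.5 rows despite φ=0.45; the published
R²=0.5/0.8 column entries for the balanced endpoint (620, 501) differ from
the computed 621, 503 by one or two counts; the published validation minimum
288 for NB relapse/progression is inconsistent with its own paired
desirable value and with `ceil(100/0.2575) = 389`, and is treated as a
typographical error; and a handful of 10/5-EPP cells differ by one count
from the exact ceilings, consistent with intermediate rounding in the
original tabulation.

## Testing strategy

The criteria are verified by a dual route: the package uses closed forms,
while `tests/oracles.py` restates each criterion as "the smallest integer n
satisfying its defining inequality", solving the shrinkage fixed point
numerically (Brent's method) and scanning integers. The two routes agree on
all eleven endpoints; the four survival sizes are additionally pinned in
`tests/fixtures/survival_reference_synthetic.json` (a synthetic fixture
generated once by the numerical oracle). Property tests (hypothesis, fixed
profiles) cover prevalence symmetry, monotonicities of the rate and size
functions, EPP-rule ratios, and conversion round-trips. Survival sizes are
checked to within 1% of the published case-study values rather than exactly,
because the original report's exact criterion implementations are not
printed and its survival integers sit a few counts away from every variant
examined here.
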