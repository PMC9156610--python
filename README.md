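# cpmsize

Minimum sample sizes for **developing and validating clinical prediction
models** with binary or time-to-event outcomes, computed from summary
epidemiology only — no patient-level data required.

The package was built around a paediatric-oncology planning problem
(neuroblastoma and diffuse intrinsic pontine glioma endpoints, shipped as a
bundled scenario registry), but every calculation takes plain numeric inputs
and applies to any prediction-model planning exercise: radiomics, clinical
scores, registry studies.

## The calculations

**Development (multi-criterion).** For a model with `p` candidate predictor
parameters, anticipated Cox–Snell fit `R²_CS`, and target shrinkage `S`
(default 0.9), three criteria are evaluated and the largest n wins:

1. expected shrinkage of fitted coefficients at least `S`:
   `n = p / ((S − 1) · ln(1 − R²_CS / S))`;
2. small optimism `δ` (default 0.05) in the apparent Nagelkerke R²: the same
   formula with `S` replaced by `S₂ = R²_CS / (R²_CS + δ · max R²_CS)`;
3. precise overall risk: binary `n = (1.96/m)² · φ(1−φ)` with margin `m`
   (default 0.05); time-to-event, the smallest `n` whose 95% interval for the
   cumulative risk `F(t*) = 1 − exp(−λ t*)` (log-scale interval
   `λ·exp(±1.96/√E)`, `E = n·λ·mean follow-up` events) has half-width ≤ `m`.

The anticipated fit is specified on the Nagelkerke scale and converted via
`R²_CS = R²_Nagelkerke × max(R²_CS)`, where the ceiling `max(R²_CS)` depends
on the outcome: `1 − exp(2(φ ln φ + (1−φ) ln(1−φ)))` for a binary outcome
with proportion φ, and `1 − exp(2e(ln e − 1))` for a survival outcome with
`e = λ ×` mean follow-up expected events per subject.

**Person-time rate.** Survival planning needs the incidence rate `λ`, which
is rarely published. It is approximated from the outcome proportion `p`,
median time-to-event and median follow-up:
`λ = p / (p·t_event + (1−p)·t_follow-up)` — each event contributes the median
event time of person-time, each non-event the median follow-up.

**Rules of thumb and validation.** For comparison, the classic 10
events-per-predictor rule and its 5-EPP relaxation (`n = ceil(EPP·p/φ)`), and
events-based validation cohort sizes (`n = ceil(100/φ)` minimum,
`ceil(200/φ)` desirable).

**Sensitivity sweeps** over the predictor count (5–30), the anticipated
Nagelkerke R² (0.15–0.8) and, for survival models, the ratio of mean
follow-up to the prediction horizon (1–4).

## Worked example

```python
>>> from cpmsize import develop_binary, validation_n, person_time_rate
>>> res = develop_binary(n_predictors=30, prevalence=0.5, r2_nagelkerke=0.3)
>>> res.criterion_sizes
{'shrinkage': 1043, 'optimism': 690, 'risk_precision': 385}
>>> res.final_n, res.epp
(1043, 17.38)
```

The shrinkage criterion dominates: 1043 patients are needed to develop a
30-predictor model for a 50%-prevalent outcome while keeping expected
shrinkage ≥ 0.9, which implies 17.38 events per predictor — well above the
classic 10-EPP rule's 600 patients, illustrating why EPP rules are not a
reliable shortcut.

From the command line, the same numbers plus a survival example:

```sh
$ cpmsize develop --scenario hr_nb_mort5y
scenario        final_n shrinkage  optimism  risk_precision  epp
hr_nb_mort5y    1043    1043       690       385             17.38
$ cpmsize rate --prevalence 0.307 --median-event-time 24.2 --median-follow-up 60
0.0063
$ cpmsize validate --prevalence 0.169
592     1184
```

The rate line reads: with 30.7% of subjects reaching the event at a median of
24.2 months and the rest followed a median of 60 months, the cohort generates
0.0063 events per person-month. The validation line: a 16.9%-prevalent
outcome needs 592 patients for 100 validation events, 1184 for 200.

`cpmsize report` writes all four summary tables (rates, development sizes per
method, R² sensitivity, validation sizes) for the bundled registry or a
`--config` YAML of your own scenarios; output is deterministic and
byte-stable.

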