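# The eleven PRIMAGE clinical endpoints (neuroblastoma, high-risk
# neuroblastoma, diffuse intrinsic pontine glioma).
#
# Prevalences are stored at the precision reported in the source text of the
# epidemiological review, not at table-rounded display precision: NB
# relapse/progression is 0.2575 (25.75%), even though summary tables often
# show 0.258.  Times are months.  n_predictors / r2_nagelkerke /
# shrinkage_target are omitted and take the defaults (30 / 0.3 / 0.9).

- id: nb_mort5y
  label: NB 5-year mortality risk
  tumour: NB
  outcome_kind: binary
  prevalence: 0.307

- id: nb_relapse
  label: NB relapse/progression risk
  tumour: NB
  outcome_kind: binary
  prevalence: 0.2575   # text precision; 0.258 when rounded for display

- id: nb_death_tte
  label: NB time to death
  tumour: NB
  outcome_kind: time_to_event
  prevalence: 0.307
  median_time_to_event: 24.2
  median_follow_up: 60
  prediction_timepoint: 24
  study_follow_up: 24

- id: hr_nb_mort5y
  label: HR-NB 5-year mortality risk
  tumour: HR-NB
  outcome_kind: binary
  prevalence: 0.5

- id: hr_nb_relapse
  label: HR-NB 5-year relapse/progression risk
  tumour: HR-NB
  outcome_kind: binary
  prevalence: 0.408

- id: hr_nb_relapse_tte
  label: HR-NB time to relapse/progression
  tumour: HR-NB
  outcome_kind: time_to_event
  prevalence: 0.561
  median_time_to_event: 19.08
  median_follow_up: 72.12
  prediction_timepoint: 24
  study_follow_up: 24

- id: dipg_mort1y
  label: DIPG 1-year mortality risk
  tumour: DIPG
  outcome_kind: binary
  prevalence: 0.45

- id: dipg_mort2y
  label: DIPG 2-year mortality risk
  tumour: DIPG
  outcome_kind: binary
  prevalence: 0.169

- id: dipg_prog1y
  label: DIPG 1-year progression risk
  tumour: DIPG
  outcome_kind: binary
  prevalence: 0.235

- id: dipg_death_tte
  label: DIPG time to death
  tumour: DIPG
  outcome_kind: time_to_event
  prevalence: 0.169
  median_time_to_event: 11.4
  median_follow_up: 24
  prediction_timepoint: 24
  study_follow_up: 24

- id: dipg_prog_tte
  label: DIPG time to progression
  tumour: DIPG
  outcome_kind: time_to_event
  prevalence: 0.235
  median_time_to_event: 7.7
  median_follow_up: 12
  prediction_timepoint: 12
  study_follow_up: 12
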