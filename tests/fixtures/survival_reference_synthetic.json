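{
  "_comment": "Synthetic reference fixture: final development sample sizes for the four time-to-event scenarios, generated once by the independent numerical oracle in tests/oracles.py (fixed-point shrinkage solve + integer scan per criterion), not by the package's closed forms. Inputs: 30 predictors, Nagelkerke R2 0.3, shrinkage target 0.9, optimism and risk margins 0.05, full-precision person-time rates, prediction time point and mean follow-up as in the bundled registry.",
  "inputs": {
    "n_predictors": 30,
    "r2_nagelkerke": 0.3,
    "shrinkage_target": 0.9,
    "optimism_margin": 0.05,
    "risk_margin": 0.05
  },
  "final_n": {
    "nb_death_tte": 1394,
    "hr_nb_relapse_tte": 1052,
    "dipg_death_tte": 1272,
    "dipg_prog_tte": 1126
  }
}
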