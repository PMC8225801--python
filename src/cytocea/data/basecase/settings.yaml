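settings:
  start_age: 69
  cohort_size: 6834.0
  discount_rate: 0.035
  cycle_length: 1.0
  age_cap: 100
  wtp_threshold: 20000.0
accuracy:
  sensitivity: 0.799
  specificity: 0.924
  endoscopy_sensitivity: 1.0
  endoscopy_specificity: 1.0
trial:
  n_invited: 6834.0
  n_swallowed: 1654.0
  n_endoscopy_intervention: 198.0
  n_endoscopy_usual: 16.0
  n_repeat_tests: 202.0
  n_repeat_endoscopies: 23.0
  uptake: 0.242
  endoscopy_attendance: 0.8959276018099548
  detected:
    intervention:
      NDBE: 123.0
      LGD: 1.0
      HGD: 3.0
      EarlyEAC: 4.0
    usual:
      NDBE: 11.6
      LGD: 0.0
      HGD: 0.0
      EarlyEAC: 4.0
  repeat_detected_delta:
    LGD: 0.1
    HGD: 1.0
    EarlyEAC: 2.0
budget:
  eligible_patients: 262941.0
  horizon_years: 29.0
prevalence:
  NDBE: 0.08290898448931812
  LGD: 0.0006731050629206906
  HGD: 0.002019315188762072
  EarlyEAC: 0.0026924202516827624
ppi_states:
- NoBE
- NDBE
- LGD
- HGD
- EarlyEAC
psa:
  n_draws: 1000
meta:
  sensitivity:
    low: 0.764
    high: 0.83
    distribution: beta
    provenance: trial-publication
  specificity:
    distribution: beta
    provenance: trial-publication
  uptake:
    low: 0.1
    high: 0.5
    distribution: beta
    provenance: trial-publication
  endoscopy_attendance:
    distribution: beta
    provenance: trial-publication
  prevalence_be:
    low: 0.04
    high: 0.12
    distribution: beta
    provenance: trial-publication
  start_age:
    low: 50.0
    high: 74.0
    provenance: trial-publication
  discount_rate:
    provenance: trial-publication
  wtp_threshold:
    provenance: trial-publication
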