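{
  "comment": "Admission-phase cohort calibration for the synthetic scenario: daily mean percent heart-rate reserve overall and by period, daily MSDA component means (arbitrary device-scaled units), and the scheduled training time consistent with the intensity decomposition.",
  "hrr_total_pct": 11.05,
  "hrr_training_pct": 22.13,
  "hrr_nontraining_pct": 9.47,
  "msda_total": 13.09,
  "msda_training": 4.44,
  "msda_nontraining": 8.65,
  "msda_total_4w": 17.08,
  "msda_training_4w": 7.67,
  "msda_nontraining_4w": 9.41,
  "training_minutes_per_day": 180
}
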