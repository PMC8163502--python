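# Demo pipeline configuration (desk scale; completes in ~2 min on one CPU).
# Any omitted key keeps its default; unknown keys are rejected.
seed: 1
n_eeg_subjects: 3
n_cognitive_per_arm: 15
n_actigraphy_per_group: 10
actigraphy_days: 2
draws: 1000
warmup: 400
eeg_measures: [PE, LZC]
recovery_tests:
  - [AM, accuracy]
  - [DSST, accuracy]
  - [PVT, accuracy]
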