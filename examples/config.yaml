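# Full-pipeline configuration for `mrtmod run-all --config ... --out ...`.
# Omitted fields fall back to the calibrated study defaults.
design:
  n_participants: 200      # study scale is 1565
  n_weeks: 26
  daily_prob: 0.5
  seed: 11
missingness: default       # "none" for a complete panel
analysis:
  outcome: mood            # mood | steps | sleep_minutes
  transform: none          # sqrt for steps/sleep
  treatment: multi         # multi | binary
imputation:
  M: 20
  seed: 12
report:
  grid: [3, 4, 5, 6, 7, 8, 9]
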