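# Demo study configuration for the command-line pipeline:
#   lamodc all --config examples/study.yaml --out results_demo --seed 1234
# Two participants, GE-BOLD-like contrast only, 5 runs per session.
seed: 1234
patch:
  n_x: 48
  n_y: 48
  spacing_mm: 0.3
  thickness_mm: 2.0
study:
  n_participants: 2
  sessions_per_contrast: 2
  runs_per_session: 5
  contrasts: [GE_BOLD]
decoder:
  n_features: 100
stats:
  n_perm: 5000
  n_boot: 1000
stages:
  write_maps: false
  sweep: false
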