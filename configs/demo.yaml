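# Demo pipeline configuration: every stage on a small synthetic session.
#   sniffsearch run --config configs/demo.yaml --out artifacts/
seed: 7
stages:
  simulate:
    n_trials: 12
    make_traces: true
    pid_sample_rate: 600.0
    plume:
      n_trials_per_bin: 4
      pid_sample_rate: 400.0
  sniff: {}
  kinematics: {}
  fit:
    S: 3
    n_iter: 40
    n_burn: 25
  states: {}
  spatial:
    bin_cm: 0.5
  decode:
    n_shuffles: 25
  plume: {}
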