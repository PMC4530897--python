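# Demo pipeline configuration: one synthetic subject, a decision-stage ROI
# and a pure-noise control ROI.  `stagedisc run --config examples/config.yaml
# --out results/` emits per-subject and group TSV tables plus provenance.
seed: 42
n_subjects: 2
n_trials: 8
n_stages: 6
stage_duration_trs: 2
inter_trial_gap_trs: 5
tr_seconds: 2.0
rois:
  - name: task
    n_voxels: 24
    n_informative: 8
    effect_amplitude: 1.2
  - name: control
    n_voxels: 24
n_bootstrap: 200
n_draws: 10
lambda_reg: 0.1
xi: 0.1
max_lag_trs: 5
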