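# Demo pipeline configuration: a reduced cohort that runs all stages in
# under a minute on one CPU. Seeds are mandatory for every stochastic stage.
outdir: scratch/demo_run
cohort:
  n_subjects: 300
  n_plates: 5
  qc_per_plate: 4
  seed: 7
tracer:
  seed: 7
mouse:
  n_per_group: 8
  diet_effect: 1.1
  seed: 7
bhc:
  alpha: 1.0
  r_threshold: 0.5
opls:
  n_folds: 7
  n_perm: 100
  seed: 7
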