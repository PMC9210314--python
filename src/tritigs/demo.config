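# Desk-scale demo: every stage on a small synthetic panel, minutes on one CPU.
stages: [simulate, qc, ld, structure, pheno, gs]
outdir: tritigs_demo_out
seed: 11
sim:
  n_accessions: 200
  n_markers: 1200
  n_subpops: 5
  n_envs: 2
  field_rows: 25
  field_cols: 16
  n_reps: 2
qc:
  min_call_rate: 0.7
  min_maf: 0.05
  max_sample_missing: 0.3
ld:
  window_bp: 50000
  bin_bp: 500
  cutoff: 0.1
  alpha: 0.05
structure:
  k_min: 1
  k_max: 8
  variance_target: 0.95
  n_starts: 10
pheno:
  model: both
gs:
  models: [rrblup, gblup, gauss]
  train_sizes: [50, 100, 150]
  marker_counts: [200, 500, 1000]
  n_iterations: 5
  fixed_train_size: 150
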