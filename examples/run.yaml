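# Full pipeline over the cohort written by `morphoconn simulate`.
paths:
  volumes: demo_cohort/volumes/*_gm.nii.gz
  atlas: demo_cohort/atlas.nii.gz
  roi_table: demo_cohort/roi_table.csv
  behavior: demo_cohort/behavior.csv
  out_dir: demo_run
mc:
  grid_size: 256
  density_floor: 1.0e-10
  inclusion_threshold: 0.0
  # fwhm_mm: 8.0        # optional pre-smoothing
stats:
  outcome: bis_total
  covariates: [age, sex]      # head-size control: [age, sex, head_size]
  alpha: 0.05
  fdr_scope: hemisphere
  n_boot: 5000
  rng_seed: 42
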