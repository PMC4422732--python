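# Four synthetic chips mirroring the study's multi-chip design (scaled down
# in individuals for quick runs).  One causal HDL effect is planted on chipA.
seed: 20150506
out_dir: results/pipeline
chips:
  - chip_name: chipA
    n_probes: 45
    n_measures: 3
    n_unmappable: 4
    n_individuals: 250
  - chip_name: chipB
    n_probes: 30
    n_measures: 4
    n_unmappable: 0
    n_individuals: 250
  - chip_name: chipC
    n_probes: 30
    n_measures: 1
    n_unmappable: 0
    n_individuals: 250
  - chip_name: chipD
    n_probes: 20
    n_measures: 1
    n_unmappable: 2
    n_individuals: 250
simulation:
  maf: 0.01
  het_beta_a: 2.0
  het_beta_b: 2.0
  brightness: 1000.0
  background_level: 50.0
  noise_cv: 0.1
  outlier_rate: 0.0005
  diabetes_rate: 0.07
  common_heteroplasmy_probes: [chipA_p0020]
causal_effects:
  - probe_id: chipA_p0020
    phenotype: hdl
    beta: 3.0
qc:
  background_quantile: 0.05
  epsilon: 1.0
  outlier_k: 5.0
  outlier_max_iter: 10
  saturation_fraction_cutoff: 0.05
association:
  alpha: 0.05
  n_min: 30
  phenotypes: [tc, hdl, ldl, tg]
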