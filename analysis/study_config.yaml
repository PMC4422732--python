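# Four synthetic chips mirroring the study design: published probe totals,
# Build-38-unmappable counts and replicate measures per allele; individuals
# scaled to 600 per chip for desk-scale runs.  One common-heteroplasmy HDL
# effect is planted on the Affy6-like chip.
seed: 20150506
out_dir: results/study
chips:
  - chip_name: affy6like
    n_probes: 465
    n_measures: 3
    n_unmappable: 54
    n_individuals: 600
  - chip_name: axiomlike
    n_probes: 252
    n_measures: 4
    n_unmappable: 0
    n_individuals: 600
  - chip_name: exomelike
    n_probes: 226
    n_measures: 1
    n_unmappable: 0
    n_individuals: 600
  - chip_name: metabolike
    n_probes: 135
    n_measures: 1
    n_unmappable: 9
    n_individuals: 600
simulation:
  maf: 0.01
  het_beta_a: 2.0
  het_beta_b: 2.0
  brightness: 1000.0
  background_level: 50.0
  noise_cv: 0.1
  outlier_rate: 0.0005
  diabetes_rate: 0.07
  common_heteroplasmy_probes: [affy6like_p0100]
causal_effects:
  - probe_id: affy6like_p0100
    phenotype: hdl
    beta: 6.0
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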