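# Small synthetic demonstration run: simulate a cohort with a planted
# alcohol signal and a paired reference summary table, then QC, cell
# deconvolution, EWAS and cross-cohort concordance.
seed: 11
synthetic:
  n_samples: 120
  n_probes: 2000
  n_causal: 60
  effect_scale: 0.001
  noise_sd: 0.01
  confounder_strength: 1.0
  confounder_loading_sd: 0.008
  slide_sd: 0.004
  cell_effect_sd: 0.01
  discordant_fraction: 0.02
  reference_effect_multiplier: 0.5
  se_profile: {kind: constant, value: 0.0002}
  embed_cell_reference: true
model:
  trait: alcohol
  orientation: methylation_outcome
  covariates: [age, bmi, cell_counts]
  exposure_coding: continuous
  n_surrogates: 2
ci_level: 0.95
genomewide_threshold: 9.4e-8
power:
  alpha_family: 0.05
  m_tests: 530639
  delta: 0.05
  target: 0.80
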