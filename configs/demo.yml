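# Demo pipeline configuration: a small male cohort with one planted
# loss-of-function gene that both raises LOY risk and carries a
# quantitative-trait effect.  Runs end-to-end in well under a minute.
simulate:
  n_individuals: 2000
  n_genes: 40
  mean_variants_per_gene: 8
  seed: 11
  carrier_gene_specs:
    - gene: GENE_GIGYF1
      n_carriers: 40
      effect_quantitative: 0.93
      effect_binary: 6.10
      loy_risk_log_odds: 1.79   # ln(5.99)
      variant_plan: [[10, 1], [2, 4], [1, 22]]

pipeline:
  trait: par_loyq
  family: gaussian
  models: [loss_of_function, moderate]
  maf_max: 0.005
  maf_inclusive: true
  alpha: 1.6e-6
  analysis_sex: M
  sensitivity_gene: GENE_GIGYF1
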