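# Demo pipeline configuration: generate a synthetic cohort and run every
# stage.  Override the seed and output directory on the command line:
#   ayamel run --config examples/demo_config.yaml --seed 7 --out demo_run/
seed: 7
outdir: demo_run
synthetic:
  n_per_group: 24
  n_genes: 2000
  n_signature_genes: 100
  log2_effect: 1.5
  nb_dispersion: 0.15
  baseline_mean: 100.0
n_variants: 30
de_alpha: 0.05
min_count: 20
min_samples: 5
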