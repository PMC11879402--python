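# Small end-to-end pipeline configuration (smoke-test scale).
simulation:
  n_samples: 150
  n_genes: 50
  n_mirna: 60
  n_tf: 80
  probes_per_gene: 8
  snps_per_gene: 10
  adjacent_fraction: 0.5
seed: 0
deflation_runs: 500
k_clusters: 8
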