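# Full-pipeline configuration for `secretoscope run --config examples/run.yaml`.
# Either give real input tables under `inputs:` or a `simulate:` block.
seed: 1

simulate:
  n_cytokines: 30
  k_true: 4
  noise_sd: 0.1
  missing_fraction: 0.03
  replicates: 1

# inputs:                      # real-data alternative to `simulate`
#   secretome: data/secretome.csv
#   infiltrates: data/infiltrates.csv
#   metadata: data/metadata.csv
#   edges: data/string_edges.tsv
#   detection_floor: 3.2       # assay detection limit, pg/mL

significance:
  noise_sd: auto               # replicate-pooled when metadata allows, else spectral
  n_boot: 100

membership:
  fold: 20
  quantile: 0.2

activity:
  threshold: auto

association:
  aggregate: mean              # fragment -> tumor aggregation
  distance: chebyshev
  linkage: average
  pca_components: 2

network:
  min_score: null              # STRING confidence cutoff, e.g. 0.4
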