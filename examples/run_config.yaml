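# Full-pipeline configuration for the shipped example fixtures.
# Run from the repository root:
#   phenoconcord run --config examples/run_config.yaml --out results/example
catalog: examples/catalog.json
scores: examples/scores.csv
embeddings: examples/embeddings.tsv
biomarkers: examples/biomarkers.csv
timeseries: examples/timeseries.csv
stages: [semantic, concordance, stratification, agreement, biomarker]
seed: 0
ks: [2, 3]
n_boot: 20
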