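# Demo pipeline configuration: simulate a small seven-sample dataset and run
# every analysis stage. Keys not listed in PipelineConfig are simulator
# (SimConfig) fields.
seed: 11
outdir: runs/demo
simulate_input: true

# simulator
n_genes: 200
n_chroms: 2
mean_expression: 30.0

# analysis
normalization: spike
fold_threshold: 5.0
pseudocount: 1.0
min_denominator: 1.0
tss_window: [200, 1500]
wpas_window: [500, 300]
bin_size: 10
min_length: 1000
peak3_window: 50
left_quantile: 0.01
n_boot: 500
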