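# Example configuration for `emgintent run --config examples/run_config.yaml`
seed: 1
n_healthy: 5
n_stroke: 3
stroke_severity: 1.0
designs: [pooled_holdout, individual_holdout, cross_group]
feature: hist
n_iterations: 5
outdir: emgintent_report
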