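# Full-scale preset for the IND-ability task (positives: compounds that
# entered clinical trials; negatives: compounds stuck at the in-vivo stage).
# Source corpora are the ZINC15 "in-trials" (+) and "in-vivo-only" (-) subsets,
# cleaned with the standard workflow; printed class counts 9386/17943
# (imbalance 1.91). Not part of the test path: requires the ZINC15 download.
hidden_size: 300
depth: 2
ffn_depth: 2
learning_rate: 1.0e-3
batch_size: 500
max_epochs: 100
patience: 10
initial_fraction: 0.05
first_batch_fraction: 0.05
growth: 1.5
max_ensemble_size: 5
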