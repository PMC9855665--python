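# Full-scale preset for the market-approvability task (positives: compounds that
# reached market approval; negatives: investigational compounds that did not).
# Source corpora are the ZINC15 "world" (+) and "investigational-only" (-) subsets,
# cleaned with the standard workflow; printed class counts 5706/3680
# (imbalance 1.55). Not part of the test path: requires the ZINC15 download.
hidden_size: 300
depth: 2
ffn_depth: 2
learning_rate: 5.0e-4
batch_size: 500
max_epochs: 100
patience: 10
initial_fraction: 0.05
first_batch_fraction: 0.05
growth: 1.5
max_ensemble_size: 5
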