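# Full-scale preset for the in-vivo-ability task (positives: compounds that
# entered animal testing; negatives: purchasable compounds that did not).
# Source corpora are the ZINC15 "in-vivo" (+) and "in-stock" (-) subsets,
# cleaned with the standard workflow; printed class counts 27329/99812
# (imbalance 3.65). Not part of the test path: requires the ZINC15 download.
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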