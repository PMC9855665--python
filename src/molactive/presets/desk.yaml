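# Desk-scale preset: trains in seconds on one CPU for synthetic tasks.
hidden_size: 32
depth: 2
ffn_depth: 2
learning_rate: 1.0e-3
batch_size: 64
max_epochs: 20
patience: 5
initial_fraction: 0.05
first_batch_fraction: 0.05
growth: 1.5
max_ensemble_size: 5
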