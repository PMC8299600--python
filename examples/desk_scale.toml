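# Desk-scale pipeline settings: 30 trials, 48-feature model input, 60 epochs.
[pipeline]
n_trials = 30
max_model_features = 48

[pipeline.model]
epochs = 60
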