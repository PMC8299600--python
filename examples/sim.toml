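# Synthetic-cohort generator settings (defaults shown).
[simulate]
n_patients = 200
lam = 8.0
beta = 1.1
censor_window = 1500.0
bias_strength = 0.6
neoantigen_fraction = 0.7
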