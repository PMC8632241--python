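# simulation conditions for the end-to-end regression fixture
n_peptides: 6
seed: 42
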