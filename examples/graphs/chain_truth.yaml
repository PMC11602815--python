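k_X1: 0.35
alpha_X1: 0.25
k_X2: 0.3
alpha_X2: 0.4
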