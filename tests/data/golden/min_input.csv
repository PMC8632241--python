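input_mass,predicted_count,ci_low,ci_high
10,1,1,1
25,2,2,2
50,4,4,4
100,4,4,4
250,4,4,4
500,6,6,6
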