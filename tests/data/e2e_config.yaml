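# analysis configuration for the end-to-end regression fixture
cv_lloq_threshold: 0.20
linearity_r2_min: 0.90
ratio_orientation: light_over_heavy
rt_tolerance: 0.10
rel_area_tolerance: 0.20
detect_min_fraction: 0.50
alpha: 0.05
random_seed: 42
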