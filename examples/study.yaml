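# Scaled-down recovery-study grid: 100 uniform-range parameter sets,
# three trial numbers, KS and ML criteria, three model complexities.
# Completes on one CPU in well under an hour.
design: one_drift
population: study1
n_parameter_sets: 100
trial_numbers: [48, 200, 1000]
contamination: [none, fast, slow]
criteria: [ks, ml]
models: [4, 5, 7]
init: default
seed: 20160913
output_dir: results/study1_scaled
precision_weights: default
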