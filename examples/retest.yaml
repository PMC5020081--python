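# Reliability-ceiling simulation: 100 simulated subjects, equal
# parameters in both sessions, lexical-decision-style two-drift
# population, 5-parameter model fitted with ML.
design: two_drift
population: study2_ldt
n_parameter_sets: 100
trial_numbers: [32, 48, 100, 200, 400, 1000]
criteria: [ml]
models: [5]
seed: 20160913
output_dir: results/retest_ceiling
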