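# Default configuration for the numbered analysis scripts.
# Raw tables and other bulky intermediates land under scratch/analysis/;
# result tables land under results/.
seed: 20181108
n_stays: 3000
# extra log-odds of ICU death per hour of the longest episode below 55 mmHg,
# used by 06_threshold_gradient.py to plant a depth-severity gradient
severity_coef_per_hour: 0.15
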