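# Demo pipeline configuration for `vffr run`
seed: 7
generations: 3
noise_sd: 0.0
severity: 0.6
extent: 0.4
age: 63.61
sbp: 133.39
dbp: 84.03
hr: 65.19
mode: unsteady
cohort_n: 6
cohort_bias: 0.0
cohort_sd_patient: 0.0
cohort_sd_vessel: 0.0
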