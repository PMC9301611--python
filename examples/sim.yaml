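n_subjects: 1600
seed: 0
slodr_slope: 0.0
grade_validity: 0.5
grade_fraction: 0.25
sex_prevalence: 0.5
adhd_prevalence: 0.05
language_prevalences:
- 0.8
- 0.12
- 0.08
education_prevalence: 0.3
participation_mean: 10.0
participation_sd: 3.0
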