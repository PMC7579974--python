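# Bundled example datasets

Both files are **synthetic stand-ins**, generated from this package's own
data model with a fixed seed. They mimic the *structure* of two published
meta-analyses of the ratio of means — a 17-study mate-choice-copying
analysis (arm sizes 30–263, approximately normal outcomes) and a 34-study
low-dose-dopamine urine-output analysis (arm sizes 6–160, right-skewed
outcomes in heterogeneous units) — but they are **not** the original
arm-level data, and analyses of them do not reproduce the published
estimates.

- `mcc_female_cue_synthetic.csv` — K=17, rating-scale outcomes, small
  coefficients of variation (all precision ratios well above 3).
- `dopamine_urine_day1_synthetic.csv` — K=34, lognormal outcomes on mixed
  scales (the LRR is scale-invariant, so mixed units are fine per study).

Schema: `study_id, n_t, mean_t, sd_t, n_c, mean_c, sd_c`.
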