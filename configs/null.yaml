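# Null-calibration scenario: no storm effect at any lag.  Moderate size
# (40 ZCTAs) with larger denominators so each lag carries enough events
# for Wald intervals to be accurate; used for coverage and p-uniformity
# replicates with per-replicate seeds derived from a base seed.
n_zctas: 40
year_start: 1999
year_end: 2016
storms_per_year: 0.226
true_lag_betas: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
baseline_log_rate: -9.4
random_intercept_sd: 0.1
denominator_range: [5000, 20000]
seed: 0
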