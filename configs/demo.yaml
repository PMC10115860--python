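# Small demo scenario for the worked example: 20 ZCTAs, full 18-year
# period, respiratory-like lag profile (cumulative RR = 4.37).
n_zctas: 20
year_start: 1999
year_end: 2016
storms_per_year: 0.226
true_lag_betas: [0.0, 0.18, 0.10, 0.13, 0.22, 0.25, 0.21, 0.18, 0.13, 0.0748]
baseline_log_rate: -9.4
random_intercept_sd: 0.1
denominator_range: [2000, 10000]
seed: 7
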