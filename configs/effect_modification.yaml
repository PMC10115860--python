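# Effect-modification scenario: storm-day (lag 0) risk is doubled
# (additive log-RR of ln 2 = 0.6931) in ZCTAs above the poverty median.
# Stratified fits should recover a between-stratum lag-0 RR ratio of 2.
n_zctas: 40
year_start: 1999
year_end: 2016
storms_per_year: 0.226
true_lag_betas: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
baseline_log_rate: -9.4
random_intercept_sd: 0.1
denominator_range: [5000, 20000]
modifier_effect: 0.693147
modifier_lags: [0]
modifier_covariate: poverty
seed: 0
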