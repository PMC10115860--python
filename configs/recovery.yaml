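# Parameter-recovery scenario: a full-size synthetic study (100 ZCTAs,
# 18 years, ~4 storms per ZCTA) with a respiratory-like lag profile whose
# cumulative relative risk is exp(1.4748) = 4.37.
n_zctas: 100
year_start: 1999
year_end: 2016
storms_per_year: 0.226
windspeed_loc: 27.0
windspeed_scale: 4.2
true_lag_betas: [0.0, 0.18, 0.10, 0.13, 0.22, 0.25, 0.21, 0.18, 0.13, 0.0748]
baseline_log_rate: -9.4
dow_effects: [0.0, 0.01, 0.01, 0.0, -0.01, -0.06, -0.08]
random_intercept_sd: 0.15
denominator_range: [2000, 10000]
seed: 1999
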