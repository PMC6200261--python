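# Bundled synthetic Barents-like scenario: red-noise upstream index (AMO
# analogue), advective chain AMO -(3y)-> FSC -(1y)-> BSO, stock responding
# to FSC/BSO at lags 4/3 (7 years total from the upstream index) plus a
# negative harvest-rate effect leading by 2 years, and recruitment leading
# the stock response by 2 years.  The prediction model is the common
# lead-7 upstream-index model; screening covers the whole pathway.
mode: synthetic
scenario: {}          # generator defaults (see codcast.synthetic)
predictand: TSB
screen_predictors: [AMO, FSC, BSO]
predictors: [AMO]
lead: 7
harvest: HR
lag_range: [0, 10]
cv_n_iter: 500
cv_fit_frac: 0.8
benchmark_lags: [1, 2, 3, 4, 5, 6, 7]
n_surrogates: 300
alpha: 0.05
detrend_screening: true
detrend_prediction: false
highpass_cutoff: 5
attribution_lag_range: [0, 5]
seed: 0
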