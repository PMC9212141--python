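# Example pipeline configuration: synthetic end-to-end run.
output_dir: out
seed: 42
alpha: 0.05
period_width: 5
anchor_year: 2000
baseline_window: [2015, 2019]
anchor_mode: window_average
class_better: 0.1
class_worse: -0.1
subregion_source: covariates
paths: {}          # inputs default to <output_dir>/*.csv written by `simulate`
synthetic:
  n_countries: 40
  years: [1990, 2019]
  period_width: 5
  code: "311"
  direction: -1
  beta_gdp: -1.05
  sigma_country: 0.3
  sigma_time: 0.05
  sigma_eps: 0.1
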