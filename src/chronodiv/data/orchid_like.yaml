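# Bundled synthetic scenario: a terrestrial-orchid-like radiation.
# Crown age 65 My, Cenozoic-like cooling proxy over the same span,
# temperature-driven exponential speciation, sampling fraction 0.3,
# 100-300 sampled tips accepted.
name: orchid_like
climate:
  start: 5.0
  end: 0.0
  oscillation_amplitude: 1.0
  oscillation_period: 8.0
  oscillation_recency: 1.0
  noise_sd: 0.15
  step: 0.5
  span: 65.0
  trend_curvature: 3.5
tree:
  lambda0: 0.15
  alpha: -0.15
  mu0: 0.0
  crown_age: 65.0
  f: 0.3
  min_tips: 100
  max_tips: 300
rtt:
  n_samples: 200
  noise_sd: 0.1
  grid_step: 0.5
traits:
  n_regimes: 8
occurrences:
  spread_deg: 2.0
  n_per_species: 10
regions:
  multi_region_frac: 0.1
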