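# Demo pipeline config: generate a synthetic study, select a model,
# evaluate the design, and compute power / required-sites tables.
seed: 7

generator: {}   # defaults: 143 sites in 3 zones, 4 months of 4-6 nights

selection:
  p_candidates: [observer_experience, time_after_dusk]
  psi_candidates: [elevation, bromeliad_size]

design_k:
  p_star: [0.8, 0.9, 0.95]

simulation:
  site_grid: [50, 150]
  occasion_grid: [2, 4, 6]
  n_iter: 500

power:
  effects: [0.3, 0.2, 0.15]
  alpha: 0.1
  occasions: 20
  site_grid: [50, 143, 300]

sites:
  alphas: [0.05, 0.1, 0.2]
  powers: [0.8, 0.9, 0.95]
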