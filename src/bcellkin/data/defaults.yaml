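# Package defaults for quantities the published analysis leaves unprinted.
calibration:
  # steady-state anchor: splenic mature B-cell total (cells)
  anchor_splenic_mature: 2.0e+7
  # logistic occupancy lambda = 1 - (B_oe + B_Mrec)/K at steady state
  occupancy: 0.5
depletion:
  # survival fraction per compartment under anti-CD20 depletion
  pro_pre: 1.0
  immature: 0.5
  mature_recirculating: 0.0
  transitional: 0.0
  splenic_mature: 0.0
design:
  # 34 days between depletion and the start of labeling, in 6-h units
  recovery_units: 136.0
  # 7 days of continuous labeling
  labeling_units: 28.0
  measurement_days: [2.0, 4.0, 7.0]
noise:
  # per-mouse Gaussian scatter of measured labeled fractions
  sd: 0.03
cohort:
  mice_per_time_point: 8
sampling:
  # Latin hypercube candidates per fit
  n_candidates: 10000
  # sampled range = published CI widened by +/-50% of its width, floored at 0
  ci_widen: 0.5
  delta_r_range: [0.0, 0.1]
  # steady-state filter half-width around the reference totals
  totals_relative_width: 0.5
profile:
  grid_size: 41
  n_draws: 500
  n_rounds: 2
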