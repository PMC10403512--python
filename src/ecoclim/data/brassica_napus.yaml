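# Oilseed rape (Brassica napus L.) parameter set for the weekly
# growth/stress suitability model.  Temperature thresholds in degC,
# moisture thresholds as proportions of soil moisture-holding capacity,
# stress rates per week.  low/high are the published sensitivity-analysis
# perturbation values (+/-1 degC for temperature thresholds, +/-10% otherwise).
parameters:
  dv0: {low: 4, value: 5, high: 6}        # lower temperature limit
  dv1: {low: 9, value: 10, high: 11}      # lower optimal temperature
  dv2: {low: 22, value: 23, high: 24}     # upper optimal temperature
  dv3: {low: 26, value: 27, high: 28}     # upper temperature limit
  sm0: {low: 0.09, value: 0.1, high: 0.11}   # limiting low soil moisture
  sm1: {low: 0.18, value: 0.2, high: 0.22}   # lower optimal soil moisture
  sm2: {low: 0.72, value: 0.8, high: 0.88}   # upper optimal soil moisture
  sm3: {low: 2.25, value: 2.5, high: 2.75}   # limiting high soil moisture
  ttcs: {low: 0.9, value: 1, high: 1.1}      # cold stress temperature threshold
  thcs: {low: -0.000081, value: -0.00009, high: -0.000099}  # cold stress rate
  tths: {low: 26, value: 27, high: 28}       # heat stress temperature threshold
  thhs: {low: 0.0009, value: 0.001, high: 0.0011}           # heat stress rate
  smds: {low: 0.09, value: 0.1, high: 0.11}  # dry stress threshold
  hds: {low: -0.0045, value: -0.005, high: -0.0055}         # dry stress rate
  smws: {low: 2.25, value: 2.5, high: 2.75}  # wet stress threshold
  hws: {low: 0.0018, value: 0.002, high: 0.0022}            # wet stress rate
hydrology:
  soil_capacity: 100.0
  sm_init: 0.5
  sm_cap: 4.0
  pet_coeff: 1.0
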