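# Shipped genotype parameter sets for the synthetic cohort generator.
#
# These are CALIBRATION VALUES for the demo cohorts (occupancy targets,
# rebound gains, SD band gains, dark-delta ratios, ICC fraction), not
# measurements produced by this package.  Occupancies are (wake, NREMS,
# REMS) fractions per 12-h window; bout scales are mean bout lengths in
# 4-s epochs per (W, N, R); homeostat time constants are hours.
genotypes:
  genotype_a:
    state_occupancy:
      BSL-L:  [0.382, 0.468, 0.150]
      BSL-D:  [0.779, 0.193, 0.028]
      SD-L:   [0.9887, 0.0113, 0.0]
      Rec-D1: [0.580, 0.327, 0.094]
      Rec-L:  [0.407, 0.445, 0.148]
      Rec-D2: [0.733, 0.229, 0.039]
    bout_scale:
      BSL-L:  [60, 50, 20]
      BSL-D:  [140, 30, 15]
      Rec-D1: [100, 30, 15]
      Rec-L:  [60, 50, 20]
      Rec-D2: [140, 30, 15]
    homeostat: {lower: 0.6, upper: 2.8, tau_rise_h: 8.0, tau_decay_h: 1.5, s0: 1.6}
    rebound_gain: 1.80
    sd_band_gains: {upper_theta: 2.4, beta_2: 1.25, gamma_1: 1.20, onset_h: 0.5}
    tpf_hz: 7.08
    artifact_rate: 0.03
    icc_fraction: 0.48
    period_hr: 23.7
    light_slope: 0.12
    dark_delta_pct: 142.6
  genotype_b:
    state_occupancy:
      BSL-L:  [0.387, 0.461, 0.152]
      BSL-D:  [0.770, 0.201, 0.028]
      SD-L:   [0.992, 0.008, 0.0]
      Rec-D1: [0.576, 0.323, 0.101]
      Rec-L:  [0.412, 0.421, 0.168]
      Rec-D2: [0.716, 0.239, 0.046]
    bout_scale:
      BSL-L:  [60, 50, 20]
      BSL-D:  [140, 30, 15]
      Rec-D1: [100, 30, 15]
      Rec-L:  [60, 50, 20]
      Rec-D2: [140, 30, 15]
    homeostat: {lower: 0.6, upper: 2.8, tau_rise_h: 8.0, tau_decay_h: 1.5, s0: 1.6}
    rebound_gain: 1.6846
    sd_band_gains: {upper_theta: 1.4, beta_2: 1.15, gamma_1: 1.10, onset_h: 0.5}
    tpf_hz: 6.84
    artifact_rate: 0.03
    icc_fraction: 0.48
    period_hr: 23.7
    light_slope: 0.12
    dark_delta_pct: 148.8
  genotype_c:
    state_occupancy:
      BSL-L:  [0.409, 0.446, 0.144]
      BSL-D:  [0.763, 0.206, 0.031]
      SD-L:   [0.9916, 0.0084, 0.0]
      Rec-D1: [0.534, 0.364, 0.102]
      Rec-L:  [0.423, 0.419, 0.158]
      Rec-D2: [0.685, 0.264, 0.051]
    bout_scale:
      BSL-L:  [60, 50, 20]
      BSL-D:  [140, 30, 15]
      Rec-D1: [100, 30, 15]
      Rec-L:  [60, 50, 20]
      Rec-D2: [140, 30, 15]
    homeostat: {lower: 0.6, upper: 2.8, tau_rise_h: 8.0, tau_decay_h: 1.5, s0: 1.6}
    rebound_gain: 1.9815
    sd_band_gains: {upper_theta: 2.4, beta_2: 1.35, gamma_1: 1.30, onset_h: 0.5}
    tpf_hz: 7.08
    artifact_rate: 0.03
    icc_fraction: 0.48
    period_hr: 23.7
    light_slope: 0.12
    dark_delta_pct: 146.1
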