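# Retentostat study configuration.
# Units: volumes L, flow L/h, concentrations g/L, rates h^-1 or g/g/h.
reactor:
  V: 1.4           # bioreactor working volume
  phi_V: 0.035     # feed flow rate -> D = 0.025 h^-1
feed:
  V_S: 1.2         # mixing-vessel working volume
  phi_V: 0.035
  C_S_MC: 10.0     # chemostat-phase reservoir glucose
  C_S_MR: 5.0      # retentostat-phase reservoir glucose
chemostat:
  m_S: 0.0100      # maintenance coefficient at fast growth
  Y_max: 0.584     # maximum biomass yield on glucose
  D_levels: [0.025, 0.05, 0.075, 0.10]
  replicates: 2
retentostat:
  m_S: 0.0031      # maintenance plateau at near-zero growth
  k_d: 6.0e-5      # first-order death rate
  t_end: 600.0     # 25 days
  enabled: true
maintenance:       # growth-rate-dependent m_S used as synthetic truth
  m_S_high: 0.0100
  m_S_low: 0.0031
  mu_mid: 0.045
  steepness: 200.0
  enabled: true
noise:
  cv: 0.03         # multiplicative CV on biomass/feed measurements
  viability_sd: 0.005
seed: 42
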