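# Scenario presets.
#
# Hormone-perturbation scenarios use the published parameter table for the
# figure-3/6/7 models; refit scenarios use the table for the figure-9
# transport-rate series (smaller time step, hence the smaller per-step
# constants).  Fields omitted in a scenario inherit the wild-type value of
# its family.  All transport/decay constants are per-simulation-step
# increments; dt sets the number of integration steps per plastochron.

defaults: &defaults
  H_apex_mu: 80.0
  H_apex_sigma: 20.0
  H_mu: 20.0
  H_sigma: 4.5
  T_mu: 3.0
  T_sigma: 0.8
  v: 0.01
  K_A: 0.05
  K_B: 0.05
  dt: 0.005
  plastochron: 1.0
  basal_zone_depth: 5
  basal_T_factor: 0.1
  growth_delay_max: 4000       # simulation steps (20 plastochrons)
  total_steps: 8000            # 40 plastochrons
  length_range: [20, 40]

scenarios:
  wild_type:
    <<: *defaults

  # Auxin-synthesis perturbations: scaled apical and lateral source levels.
  shi2_1:
    <<: *defaults
    H_apex_mu: 48.0
    H_apex_sigma: 12.0
    H_mu: 12.0
    H_sigma: 2.7
  SHI_ox_5:
    <<: *defaults
    H_apex_mu: 240.0
    H_apex_sigma: 60.0
    H_mu: 60.0
    H_sigma: 13.5

  # Cytokinin perturbations: scaled branching threshold.
  CKX2oe:
    <<: *defaults
    T_mu: 0.45
    T_sigma: 0.2
  IPT1oe:
    <<: *defaults
    T_mu: 5.4
    T_sigma: 0.8

  # Transport-direction variants (no basal inhibitor, as in the
  # direction-of-transport simulations).  Total transport K_A + K_B is held
  # at the wild-type 0.1 while the ratio is set.
  ka_kb_3:
    <<: *defaults
    K_A: 0.075
    K_B: 0.025
    basal_T_factor: 1.0
  ka_kb_100:
    <<: *defaults
    K_A: 0.0990099
    K_B: 0.0009901
    basal_T_factor: 1.0
  ka_kb_1_3:
    <<: *defaults
    K_A: 0.025
    K_B: 0.075
    basal_T_factor: 1.0
  ka_kb_1_100:
    <<: *defaults
    K_A: 0.0009901
    K_B: 0.0990099
    basal_T_factor: 1.0
  no_basal_inhibitor:
    <<: *defaults
    basal_T_factor: 1.0

  # Refitted family for the transport-rate (plasmodesmal permeability)
  # series; dt = 0.001, i.e. 1000 steps per plastochron.
  wild_type_refit: &refit
    <<: *defaults
    H_apex_mu: 30.0
    H_apex_sigma: 10.0
    H_mu: 5.0
    H_sigma: 1.5
    T_mu: 0.7
    T_sigma: 0.2
    v: 0.002
    K_A: 0.025
    K_B: 0.025
    dt: 0.001
    growth_delay_max: 20000
    total_steps: 40000
  ddg10:
    <<: *refit
    K_A: 0.045
    K_B: 0.045
  ddg25:
    <<: *refit
    K_A: 0.07
    K_B: 0.07
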