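grid:
  nx: 1024
  ny: 2048
  dx_m: 0.5
  dy_m: 0.5
params:
  dt_s: 0.0125
  phi_s: 44712.0
  t_end_yr: 50.0
  D0_m2_per_s: 1.0e-07
  DB_m2_per_s: 6.0e-09
  DU_m2_per_s: 0.5
  ES_s_per_m2: 0.00025
  EB_s_per_m2: 1.0e-05
  g_m_per_s2: 9.81
  H0_m: 0.02
  Hc_m: 0.001
  Hin_m_per_s: 1.0e-05
  k_per_m2: 1500.0
  nb_s_per_m13: 0.016
  nv_s_per_m13: 0.2
  pD: 0.99
  pE: 0.9
  pest: 0.002
  Qq_m: 0.02
  Qs_m: 0.0006
  rho_kg_per_m3: 1000.0
  r_per_s: 3.2e-08
  Sin_m_per_s: 5.0e-09
run:
  seed: 0
  snapshot_every_yr: 1.0
  veg_dynamics: true
  advection: central
  engine: auto
  checkpoint_path: null
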