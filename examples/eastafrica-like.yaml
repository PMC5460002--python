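# Synthetic configuration tuned to an East-African-rift-like regime:
# semi-arid mean recharge with a strong spatial gradient, groundwater
# response times spanning several orders of magnitude, clustered water
# features on rough volcanic terrain.
synth_springs:
  n_springs: 450
  B_range_m: [500.0, 15000.0]
  k0_m_per_s: [1.0e-7, 1.0e-4]
  area_coeff: 0.06
  area_scatter_sd_log10: 0.4
  recharge_mean_mm: 49.0
  recharge_gradient_mm: 80.0
  recharge_max_mm: 250.0
synth_landscape:
  shape: [128, 128]
  relief_m: 600.0
  n_clusters: 5
scenario_ids: [Run-1, Run-2, Run-3, Run-4]
r_min_mm: 1.0
threshold_Q: 1000.0
p_max_y: 23000.0
abm:
  n_per_tick: 4000
  ticks: 100
  energy: 150
  max_turn_deg: 20.0
reps: 1
seed: 7
out_dir: hydrorefugia_out
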