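# Desk-scale mineralized fibril: 7 molecules per cross-section,
# 5 D-periods, edge-nucleated mineral at 60% gap filling.
layout:
  n_molecules: 7
  n_periods: 5
mineral:
  morphology: reference_edge
  c_mineral: 60.0
crosslinks:
  n_age_per_tc: 0
protocol:
  dt: 10.0
  T: 300.0
  damping: 1000.0
  v_pull: 1.0e-3
  max_strain: 0.6
  sample_every: 200
  rebuild_every: 50
equil_steps: 1500
seed: 3
output_dir: runs/mini_c60
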