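# Full pipeline run: 20 cells in the 100-um circular adhesive island,
# 1 h of simulated timelapse at 10-s frames.
seed: 11
output_dir: confinetrack_out
region:
  kind: disk
  center_um: [0.0, 0.0]
  radius_um: 50.0
simulation:
  n_cells: 20
  duration: 3600.0
  division:
    enabled: false
analysis:
  n_rings: 4
  grid_step_um: 0.5
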