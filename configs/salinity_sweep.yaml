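# One-hour salinity sweep (0 - 1.3 M NaCl) with polystyrene-bead controls.
# Cell membrane conductance first rises toward moderate salinity (high
# permeability, low transparency) and falls again at the extremes; beads are
# insensitive to the suspending medium.
seed: 19
output_dir: results/salinity_sweep
populations:
  - {group: salt_0.0M, n_cells: 150, g_mem_s_per_m2: {median: 30.0, sigma: 0.25}}
  - {group: salt_0.1M, n_cells: 150, g_mem_s_per_m2: {median: 120.0, sigma: 0.25}}
  - {group: salt_0.3M, n_cells: 150, g_mem_s_per_m2: {median: 400.0, sigma: 0.25}}
  - {group: salt_0.7M, n_cells: 150, g_mem_s_per_m2: {median: 90.0, sigma: 0.25}}
  - {group: salt_1.3M, n_cells: 150, g_mem_s_per_m2: {median: 25.0, sigma: 0.25}}
  - {group: bead_0.0M, n_cells: 150, bead: true, diameter_um: {median: 5.0, sigma: 0.01}}
  - {group: bead_0.3M, n_cells: 150, bead: true, diameter_um: {median: 5.0, sigma: 0.01}}
  - {group: bead_0.7M, n_cells: 150, bead: true, diameter_um: {median: 5.0, sigma: 0.01}}
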