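# Live vs heat-killed comparison: dead cells carry a leaky membrane
# (100x specific membrane conductance) and shrink to 0.8x diameter.
seed: 7
output_dir: results/live_dead
populations:
  - group: live
    n_cells: 300
  - group: dead
    n_cells: 300
    diameter_um: {median: 3.68, sigma: 0.03}
    g_mem_s_per_m2: {median: 500.0, sigma: 0.25}
analysis:
  transparency_freq_hz: 2.0e7
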