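# Demo experiment: three salinity-style conditions x 200 cells each.
# Membrane-conductance medians are constructed so the conditions separate
# clearly in transparency; runs end-to-end in well under five minutes.
seed: 42
output_dir: results/demo
populations:
  - group: low_salt
    n_cells: 200
    g_mem_s_per_m2: {median: 2.0, sigma: 0.25}
  - group: control
    n_cells: 200
    g_mem_s_per_m2: {median: 50.0, sigma: 0.25}
  - group: high_salt
    n_cells: 200
    g_mem_s_per_m2: {median: 500.0, sigma: 0.25}
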