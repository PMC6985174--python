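# Salinity x time design: low / control / high salt sampled at 1 h, 5 h,
# 1 d and 5 d.  Group transparencies follow the observed trajectory: the
# stressed groups sit well below control right after the shock (1 h), relax
# back to control levels by 5 h - 1 d, and fall again after 5 d when the
# stressed cultures fail to adapt.  Under the circuit model a low group
# transparency corresponds to a high effective membrane conductance.  The
# 5-day stressed groups carry a 3% outlier subpopulation that keeps a large
# diameter together with a permeable membrane.
seed: 23
output_dir: results/time_course
populations:
  - {group: low_1h,  n_cells: 150, g_mem_s_per_m2: {median: 300.0, sigma: 0.25}}
  - {group: ctrl_1h, n_cells: 150, g_mem_s_per_m2: {median: 50.0,  sigma: 0.25}}
  - {group: high_1h, n_cells: 150, g_mem_s_per_m2: {median: 350.0, sigma: 0.25}}
  - {group: low_5h,  n_cells: 150, g_mem_s_per_m2: {median: 60.0,  sigma: 0.25}}
  - {group: ctrl_5h, n_cells: 150, g_mem_s_per_m2: {median: 50.0,  sigma: 0.25}}
  - {group: high_5h, n_cells: 150, g_mem_s_per_m2: {median: 65.0,  sigma: 0.25}}
  - {group: low_1d,  n_cells: 150, g_mem_s_per_m2: {median: 55.0,  sigma: 0.25},
     diameter_um: {median: 4.75, sigma: 0.03}}
  - {group: ctrl_1d, n_cells: 150, g_mem_s_per_m2: {median: 50.0, sigma: 0.25}}
  - {group: high_1d, n_cells: 150, g_mem_s_per_m2: {median: 50.0, sigma: 0.25}}
  - {group: low_5d,  n_cells: 150, g_mem_s_per_m2: {median: 300.0, sigma: 0.25},
     diameter_um: {median: 4.8, sigma: 0.03}, outlier_fraction: 0.03}
  - {group: ctrl_5d, n_cells: 150, g_mem_s_per_m2: {median: 50.0, sigma: 0.25}}
  - {group: high_5d, n_cells: 150, g_mem_s_per_m2: {median: 280.0, sigma: 0.25},
     diameter_um: {median: 4.55, sigma: 0.03}, outlier_fraction: 0.03}
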