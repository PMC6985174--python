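# impedancyte

Multi-frequency **impedance flow cytometry** analysis: single-cell
electrical phenotyping for micron-scale cells (microalgae, bacteria-sized
particles) measured in a microfluidic channel between coplanar electrodes.
When a cell transits the sensing region it occludes part of the ionic
current, producing a negative pulse in the demodulated lock-in voltage at
each of eight excitation frequencies (500 kHz – 30 MHz).  Low-frequency
pulse depth reports cell volume (Coulter principle); high-frequency depth
reports membrane permeability and cytoplasm conductivity once the membrane
capacitance is shorted.

The package is for experimenters and method developers who want a tested,
fully synthetic-data-validated version of this analysis chain:

- **circuit model** — the cell as `C'_dl` in series with `R_mem ∥ C_mem`
  and `R_cyto ∥ C_cyto`, in (occluded) parallel with the solution branch
  `R_sol ∥ C_sol`, plus electrode double layer `C_dl`; a phenotype→element
  mapping and a Coulter-style occlusion model predict the per-frequency
  relative pulse amplitude `a(f)`;
- **synthetic data** — seeded, ground-truth-annotated multi-channel traces
  (negative Gaussian pulses, white noise, baseline drift) for designed
  populations: live/dead, salinity × time conditions, polystyrene-bead
  controls;
- **event detection** — rolling-median baseline, MAD-threshold negative-peak
  detection on the 500 kHz reference channel, per-channel peak amplitude
  `baseline − minimum` in co-registered windows, coincidence/QC filtering,
  certified against an exhaustive per-sample reference detector;
- **features** — cell *transparency*
  `T(f) = amp_rel(f) / amp_rel(500 kHz)` (a size-normalized electrical
  phenotype), cube-law size calibration `amp = k_cal·d³` and diameter
  estimation;
- **population analysis** — group summaries with both transparency
  estimators, transparency-vs-size curves, rank-sum group comparisons with
  BH correction, and quantile gating of large high-permeability outlier
  cells.

## Worked example

Run the shipped live-vs-heat-killed experiment (300 cells per group,
simulated, detected and analysed end to end):

```bash
python analysis/01_live_dead.py
```

prints

```
== live vs dead ==
 live: n= 292  transparency(20 MHz) ratio-of-means=0.711  mean-of-ratios=0.712
 dead: n= 296  transparency(20 MHz) ratio-of-means=0.389  mean-of-ratios=0.392
mean amp_rel at  500 kHz: live=0.00338 dead=0.00184 gap=45.77% of live
mean amp_rel at   20 MHz: live=0.00240 dead=0.00071 gap=70.32% of live
mean amp_rel at   25 MHz: live=0.00240 dead=0.00070 gap=70.94% of live
rank-sum transparency_20MHz: p=9.79e-98, median diff=0.326 CI=(0.316, 0.334)
```

Reading the numbers: dead cells (leaky membrane, 0.8× diameter) are less
transparent at 20 MHz (0.39 vs 0.71) because their equilibrated cytoplasm
no longer contrasts with the medium once the membrane shorts; their 500 kHz
amplitude is smaller because they are smaller; and the live–dead amplitude
gap widens from 46% at 500 kHz to ~71% at 20–25 MHz — size differences are
modest, electrical ones large.  `analysis/02_salinity_sweep.py` (bead
controls flat to 0.4% while algal conditions spread 173%) and
`analysis/03_time_course_outliers.py` (transparency trajectory over
1 h → 5 d plus outlier gating) reproduce the other two experiment designs.
All tables land under `results/`.

The same pipelines are scriptable through the CLI:

```bash
impedancyte run --config configs/demo.yaml
impedancyte simulate --config configs/demo.yaml --out out/
impedancyte detect --trace out/trace_control.h5 --config configs/demo.yaml --out out/
```

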