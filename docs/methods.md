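# Methods

`impedancyte` models and analyses multi-frequency impedance flow cytometry
of micron-scale cells: single cells transiting a microfluidic sensing region
between coplanar electrodes, interrogated simultaneously at eight
frequencies from 500 kHz to 30 MHz by a multi-tone lock-in amplifier.  The
package covers the whole chain — equivalent-circuit forward model, synthetic
demodulated traces, pulse detection and measurement, per-cell features,
population summaries — so that every analysis step can be validated against
known ground truth.

## Equivalent-circuit model

The sensing region is a lumped network.  The empty channel is a solution
resistance `R_sol` in parallel with a solution capacitance `C_sol`, in
series with the electrode double-layer capacitance `C_dl`.  A particle is a
series chain: its own double-layer capacitance `C'_dl`, the membrane
(resistance `R_mem` ∥ capacitance `C_mem`), and the cytoplasm
(`R_cyto` ∥ `C_cyto`).  Both double-layer capacitances are sized (defaults
1 nF for the cell, 120 pF for the electrodes) so they matter only below a
few kHz — well below the measurement band.

Any RC one-port has a non-increasing impedance magnitude in frequency; for
the cell chain this is the physics of *membrane shorting*: as frequency
rises the membrane capacitance conducts, and the measurement progressively
sees the cytoplasm instead of the insulating shell.

### Phenotype → circuit elements

A particle is described biophysically: diameter `d` (µm), specific membrane
conductance `g_mem` (S/m², the membrane-permeability proxy), specific
membrane capacitance `c_mem` (F/m², ~0.01 for a bilayer), cytoplasm
conductivity `σ_cyto` (S/m) and relative permittivity `ε_cyto`.  Mapping,
with membrane area `A = π d²`:

```
C_mem = c_mem · A            R_mem = 1 / (g_mem · A)
R_cyto = 1 / (σ_eff · d · k_geo)     C_cyto = ε_cyto ε₀ d · k_geo
```

`k_geo` (default 1.5, dimensionless) sets the access geometry of the
cytoplasm path, of the order of the spreading-resistance constant of a
sphere.  The scaling exponents (`C_mem ∝ d²`, `R_cyto ∝ 1/d`) are asserted
by tests.

**Ion-exchange coupling.**  A leaky membrane does more than conduct: it
lets medium ions flood the cytoplasm, so the cytoplasm of a dead or highly
permeable cell approaches the medium electrically.  The mapping captures
this with one saturating relation,

```
σ_eff = σ_med − (σ_med − σ_cyto) · exp(−g_mem / g_ref),
```

with `g_ref = 200 S/m²` and `σ_med = 1.6 S/m` (PBS).  This is the mechanism
that makes the transparency statistic (below) *decrease* monotonically in
membrane permeability, matching the observed live/dead ordering: in the
series topology alone, `g_mem` competes with `ωC_mem` at 500 kHz long
before 20 MHz, which would push the statistic the other way.  Setting
`ion_exchange: false` in the config recovers the textbook literal mapping.
The monotone non-increasing transparency-vs-`g_mem` relation holds over
`g_mem` from 1 to ~1.5×10³ S/m²; beyond that, where `σ_eff` has saturated at
the medium value, the residual direct membrane-conductance term produces a
sub-0.1% uptick, so validation sweeps use the 1–10³ S/m² range.

### Pulse amplitude (occlusion model)

A particle occludes the Coulter-style volume fraction
`φ = d³ / (width² · gap)` of the sensing region (clipped to [0, 1];
channel 30 × 8 µm, electrode gap 30 µm by default).  The occupied branch is
a volume mixture of admittances,

```
1/Z_with = (1 − φ)/Z_sol + φ/Z_cell,
a(f) = max(0, |Z_with|/|Z_sol| − 1),
```

so an insulating particle displaces conducting solution and raises the
branch impedance — reproducing the `d³` size dependence at low frequency —
while a particle electrically identical to the medium is invisible.
Amplitudes are clipped at zero because a hyper-conductive particle would
produce a positive voltage excursion that the negative-peak detector
ignores.  Output voltage is proportional to sensing-region impedance, so
`a(f)` is also the relative depth of the negative voltage pulse.  For plain
circuit analysis (`system_impedance` with no occlusion argument) the cell is
placed in ordinary parallel with the solution branch, which is the form
checked against the independent complex-arithmetic oracle.

Default element values (`R_sol = 78 kΩ`, `C_sol = 5.7 fF`) follow from the
channel geometry and PBS conductivity; they are plausible magnitudes, fully
config-overridable, and carry no claim of matching any particular
instrument.

## Synthetic traces

The generator emulates the demodulated lock-in output for designed
populations:

- **Phenotypes** are drawn from log-normal distributions (median, log-σ).
  Defaults: diameter median 4.6 µm, σ = 0.04 (the organism holds its size
  in a tight 4.5–4.8 µm band); `g_mem` median 5 S/m² (live), σ = 0.25;
  `σ_cyto` median 0.6 S/m, σ = 0.08.  Heat-killed cells are modelled as
  `g_mem` ×100 and diameter ×0.8.  Bead controls use insulating floors
  (`g_mem = σ_cyto = 10⁻⁶`, `c_mem = 10⁻⁶ F/m²`, `ε = 2.6`) and a 5 µm
  size standard matched to the cells.  An `outlier_fraction` of cells gets
  multiplicative shifts (default diameter ×1.3, `g_mem` ×10).
- **Pulses** are negative Gaussians of σ = transit_time/4 (default transit
  1 ms), centred on the sample grid, one transit per cell, with per-channel
  depth `baseline · a(f)`.  Event times are uniform conditioned on a
  minimum separation of 3 transit times, drawn by the exact
  order-statistics construction (no rejection, no silent merging).
- **Interference** is additive white Gaussian noise (default relative sd
  3.4×10⁻⁴, i.e. SNR ≈ 10 against the default live-cell reference
  amplitude of 3.4×10⁻³) plus a slow sinusoidal baseline drift (default
  0.2% at 7.3 s period).  Real instruments add lock-in carrier cross-talk,
  channel-blockage artifacts and flow-speed variation, none of which are
  modelled — passing tests show the analysis chain is correct under the
  stated noise model, not that it is robust to every instrument pathology.
- **Randomness**: one seed, split via `numpy` `SeedSequence.spawn` in a
  fixed order (population, event times, noise), so each stage is
  independently reproducible and regeneration is bit-identical.
- Sampling rate defaults to 57.6 kHz per demodulated channel.  Typical
  event rates and SNR of real instruments are not published for this class
  of device; defaults were chosen once for testability.

Every trace ships with a ground-truth log (event times, phenotypes, true
per-channel amplitudes) used by the tests and the acceptance script.

## Event detection and measurement

1. **Baseline**: rolling median (default 201 samples), edges reflected;
   robust to pulses occupying a minority of the window.
2. **Normalization**: division by the baseline, so 1.0 marks the quiescent
   level on every channel and channels with different gains are comparable.
   Raw-volt amplitudes are retained alongside.
3. **Detection** runs on the 500 kHz reference channel only — the dips are
   largest there because particle volume dominates at low frequency — after
   a moving-average pre-smoother (default 2 pulse-σ).  A sample opens a
   candidate when it falls below `1 − k·σ̂` with `σ̂ = 1.4826·MAD` and
   `k = 5`.  Maximal sub-threshold runs become windows padded by one
   transit time; windows closer than half a transit time are flagged
   *coincident*, never merged.  All channels are then measured in the same
   window, realizing the cross-frequency co-registration of simultaneous
   demodulation.  A per-sample exhaustive reference detector
   (`brute_force_detect`) certifies the vectorized path with exact window
   equality.
4. **Peak measurement**: baseline = median of the baseline series over
   guard regions flanking the window (offset 2 transit times so pulse tails
   cannot leak in); minimum = smallest sample of the smoothed channel in
   the window (earliest wins ties); amplitude = baseline − minimum, also
   divided by the baseline for the relative form.  The known attenuation of
   a Gaussian peak under the moving average is divided back out
   analytically.  At SNR 10 the median relative amplitude error is ~1.5%.
5. **QC**: events flagged coincident, inverted (positive excursion),
   saturated, over-wide (merged doublets) or spanning a baseline shift
   > 2% are rejected; every rejection is logged with its reason.

Conventions: half-open `[start, end)` windows, 0-based indices, seconds.

## Features and population analysis

- **Transparency** of an event at high frequency `f` is
  `amp_rel(f) / amp_rel(500 kHz)` — a size-normalized measure of how freely
  the field passes the cell.  Both 20 MHz (viability/stress contrasts) and
  5 MHz (membrane-permeability scatter axis) columns are emitted.  Two group
  estimators are reported: *ratio of means* (mean amplitudes first, then
  ratio — the form used for the published group averages) and *mean of
  ratios* (per-cell statistic averaged); they differ on heterogeneous
  groups and reports label which is shown.
- **Size**: the 500 kHz relative amplitude is the size proxy; a cube-law
  calibration `amp = k_cal·d³` fitted against independently known diameters
  (microscopy in the real workflow, ground truth in simulation) inverts it
  to an estimated diameter.  The cube law is the Coulter volume principle
  and matches the simulator's occlusion convention by construction; the
  residual diameter dependence of the circuit factor biases the median
  estimate by well under 1% over the 4.5–4.8 µm range.
- **Outlier gating**: within each group, events with size proxy above the
  0.90 quantile *and* 5 MHz transparency below the 0.10 quantile (high
  permeability = low high-frequency ratio under the circuit model) are
  flagged; robust median/MAD z-scores accompany the flags.  Quantile gating
  makes the rule invariant to global amplitude rescaling.  The real study
  marked such outliers by eye; the quantile rule is a reproducible stand-in,
  not a reconstruction.
- **Comparisons**: two-sided Wilcoxon rank-sum (per-cell amplitude
  distributions are right-skewed), difference of medians with a seeded
  percentile-bootstrap CI, Benjamini–Hochberg adjustment across the group
  pair × feature grid.  No significance procedure is described for the
  original experiments; this is the package's own choice.

One interpretive caveat is deliberate: a *high* ratio is called "more
transparent", yet a dead cell — more transparent to the field in the
physical sense — has a *low* ratio.  The statistic is implemented exactly
as defined and sign language is left to report text.

## Problem sizes and numerical choices

The shipped test suite and acceptance script use: 150 random parameter sets
for oracle equivalence (tolerance 10⁻⁹ relative; observed ~10⁻¹⁶), 1000
random circuits for monotonicity, one 200-event SNR-10 trace for detector
fidelity, 100 10⁴-sample traces for brute-force equality, 500 events/group
for recovery of the 4.6 µm median diameter (3% band) and of designed group
transparencies 0.4/0.6/0.5 (5% band, built by root-finding `g_mem` against
the forward model), 300+300 events for the live/dead contrast, 3×250 beads
and 3×150 cells for the control/condition spread, and 2000 events with 5%
planted outliers for gating precision/recall (0.8 band).  These sizes give
comfortable statistical margins while keeping a full run in a few minutes
on one CPU.  Ties in window minima resolve to the earliest sample; ε₀ is
fixed at 8.8541878128×10⁻¹² F/m; all quantile/robust statistics are
deterministic given data and config.

## Known limitations

- The circuit is a single-shell lumped model; no Maxwell–Wagner mixture
  theory, no finite-element field solution, no bipolar-pulse velocimetry.
- The phenotype→element mapping (in particular `k_geo` and the ion-exchange
  relation) is a modelling choice constrained by qualitative behaviour, not
  fitted to measured spectra; absolute transparency values are therefore
  not comparable to any specific instrument, only orderings and structure.
- Detection is threshold-based; no matched filtering or template matching,
  and no real-time/streaming operation.
- Dielectric inverse fitting (per-cell R/C estimation from the eight
  amplitudes) is out of scope.
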