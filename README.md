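# sparkquant

Quantitative analysis of biomolecular condensates in live-cell
fluorescence imaging, built for chemogenetic phase-separation (PS)
experiments in which a tagged transcription factor (e.g. a YAP fusion
oncoprotein) forms nuclear condensates that can be dissolved on demand.
The package is aimed at cell biologists and image analysts who need the
full quantitative chain from raw image stacks and count matrices to the
numbers a PS study reports: saturation concentrations, droplet material
properties, colocalization fractions, dissolution kinetics and the genes
whose expression depends on condensate formation itself.

## What it computes

* **Concentration calibration** — Beer–Lambert stock quantification
  (c = A / εL) and an OLS standard curve I = a·C + b from a purified-
  fluorophore dilution series, inverted to convert per-cell mean
  fluorescence (counts/pixel) to protein concentration (nM).
* **Condensate detection and the SPARK signal** — per-cell low threshold
  for the nucleus, per-cell high threshold (dilute-phase mean + k·σ,
  sigma-clipped) for condensates; SPARK signal
  S = Σ(condensate pixel intensity) / Σ(all cell pixel intensity) ∈ [0,1],
  plus the condensate/dilute density ratio.
* **Saturation concentration** — the per-cell (C, S) phase curve is fitted
  with a hinge changepoint model (S = b₀ below c_sat; b₀ + a₁x + a₂x²
  with x = 1 − c_sat/C above), grid-searched over candidate breakpoints,
  with a percentile bootstrap CI over cells; two conditions can be
  compared to measure a c_sat shift.
* **Fusion kinetics** — droplet merges are tracked, the merged object's
  aspect ratio AR(t) = 1 + (AR₀−1)·e^(−t/τ) is fitted per event, and the
  inverse capillary velocity η/γ = τ/ℓ (s/µm) is summarized over events
  (ℓ = equivalent radius of the final fused droplet).
* **Colocalization** — the directional fraction of reference condensates
  containing a punctum of another component (centroid-in-mask or
  mask-overlap rule).
* **Time courses** — per-frame SPARK signal, total cell fluorescence
  (a conservation control) and chromosome volume from an H2B channel;
  dissolution completion time and changepoint-based event-timing offsets.
* **Expression** — ΔΔCt qPCR quantification (2^(−ΔΔCt)); an in-house
  negative-binomial Wald test with median-of-ratios normalization and
  trended dispersion shrinkage, calling genes at p < 0.01, |log2FC| ≥ 0.58,
  FDR < 0.1; three-contrast set algebra isolating PS-regulated genes; and
  a hypergeometric over-representation test for user-supplied gene sets.
* **Synthetic data** — a first-class generator module producing
  ground-truthed inputs for every stage (images with a known c_sat and
  partition ratio, fusion movies with known η/γ, conservation-exact
  dissolution series, paired-channel puncta with a set colocalization
  probability, Ct tables and NB count matrices with spiked truth sets).

## Worked example

```python
import numpy as np
from sparkquant import synthetic, calibration, detection, phase

gt = synthetic.ImagingGroundTruth(csat_nM=40.0, partition_ratio=7.5, seed=1)
cells, truth = synthetic.generate_cell_images(gt, np.geomspace(5, 500, 100))
curve = calibration.fit_standard_curve(synthetic.generate_dilution_table(gt))
meas = detection.measure_cells([c.stack for c in cells], curve=curve)
est = phase.estimate_csat(phase.build_phase_curve(meas), n_bootstrap=1000, seed=1)
print(f"c_sat = {est.csat_nM:.1f} nM (95% CI {est.ci_low_nM:.1f}-{est.ci_high_nM:.1f})")
```

prints

```
c_sat = 39.7 nM (95% CI 37.1-42.2)
```

i.e. the hinge fit recovers the generator's 40 nM saturation
concentration from 100 noisy cells: below ~40 nM the cells show no
condensates and SPARK ≈ 0; above it the condensate-resident fraction
rises continuously, and the breakpoint of that rise is the estimate.

The same round trip is available from the shell, e.g. for qPCR:

```sh
sparkquant simulate qpcr --seed 3 --out q
sparkquant qpcr q/ct_table.csv --target CTGF --target CYR61
```

```
 gene     ddct  relative_expression  percent_change  p_value
 CTGF 2.588500             0.166259      -83.374147 0.000775
CYR61 1.602265             0.329359      -67.064056 0.008099
```

— triplicate Ct tables generated at 0.16× and 0.30× fold changes are
read back as 83% and 67% expression decreases by the 2^(−ΔΔCt) method.

`sparkquant all --seed 1 --out results` runs every stage end to end and
writes per-stage CSV/JSON outputs plus a provenance manifest.

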