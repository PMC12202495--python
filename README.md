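# mitoquant

Quantitative pipelines for asking how the metabolic division of labor
between astrocytes and neurons differs across species — in particular in
the hypoxia-tolerant brain of deep-diving seals, where the astrocyte–neuron
lactate shuttle appears to run in *reverse* (rANLS): hypoxic neurons export
lactate via the transporter MCT4, and aerobically capable astrocytes
consume it. Testing that idea quantitatively takes four kinds of evidence,
and `mitoquant` implements the analysis layer for each:

1. **Mitochondrial morphometry** (`mitoquant.morphometry`) — from
   multi-channel fluorescence z-stacks: cell regions are segmented from a
   marker channel (GFAP → astrocytes, MAP2 → neurons), mitochondria are
   detected in a TOMM20 channel by max z-projection → radius-4 median
   background subtraction → isodata auto-threshold → distance-transform
   watershed → calibrated particle measurement, with particles < 0.4 µm²
   discarded as pixel noise. Outputs: particle count, density per mm² of
   cell area, and size statistics.
2. **Fractional marker area** (`mitoquant.fractional_area`) — the
   per-cell statistic `f = #(pixels > t) / #pixels` inside a manually
   annotated cell, with threshold `t = mean(3 background samples) × SNR`.
3. **SUIT respirometry** (`mitoquant.respirometry`) — per-state O₂ flows
   (Ce, CI_L, CI_P, CI+CII_P, CII_P, CII_E) extracted as least-squares
   slopes of the O₂ trace between titration injections, normalized per
   10⁶ cells; the cytochrome-c membrane-integrity rule (> 10 % flow
   increase ⇒ exclude); and the derived efficiencies
   rel CI = CI_P / CI+CII_P, coupling = 1 − CI_L/CI_P,
   %ΔADP = (CI_P − Ce)·100/Ce, %Δsuccinate = (CI+CII_P − CI_P)·100/CI_P.
4. **Expression comparison** (`mitoquant.expression`) — two-group TPM
   tables: TPM > 0 filter, signed fold change (±ratio, sign = which group
   is higher), Benjamini–Hochberg FDR, differential-expression call at
   FDR < 0.05.

A statistics layer (`mitoquant.stats`) supplies the gated one-sided
t-test (Shapiro–Wilk + Levene gates), one-way ANOVA with Tukey HSD, and
Poisson/Gamma log-link group-mean models producing least-squares means,
pairwise contrasts (animal-level cluster bootstrap for uncertainty) and
back-transformed means. A synthetic-data generator
(`mitoquant.synthdata`) produces ground-truthed images, SUIT traces and
TPM tables so the whole pipeline is testable without any microscope or
oxygraph.

## Worked example

Generate a synthetic cortical field with 30 programmed mitochondria
inside a known astrocyte mask, write it as TIFF, and run the morphometry
pipeline from the shell:

```sh
mitoquant mito --stack field.tif --marker gfap
# n=30 density_per_mm2=3162.42 mean_size_um2=1.25
```

All 30 programmed particles are recovered; the density is the count over
the segmented cell area (here 30 / 9486 µm² ≈ 3162 per mm²) and the mean
cross-sectional area matches the programmed truth exactly. The same
library calls are available in Python:

```python
from mitoquant import morphometry
from mitoquant.synthdata import random_image_truth, generate_tissue_image

truth = random_image_truth(seed=1, shape=(512, 512), n_inside=30)
stack, realized = generate_tissue_image(truth, seed=1)
rois, particles, summary = morphometry.run_pipeline(stack, marker="gfap")
print(summary.n_particles, round(summary.density_per_mm2), summary.mean_size_um2)
# 30 3162 1.25
```

Extracting flows from a synthetic SUIT trace with programmed per-state
flows (pmol·s⁻¹ per 10⁶ cells):

```sh
mitoquant resp --trace trace.csv --events events.csv --cells 0.55
# {"Ce": 11.0, "CI_L": 9.0, "CI_P": 28.0, "CIcytc": 29.0,
#  "CIplusCII_P": 52.0, "CII_P": 41.0, "CII_E": 61.0}
```

Each flow is recovered to the programmed value (relative error < 1e-6);
`resp_metrics.json` additionally carries the derived efficiencies, e.g.
rel CI = 28/52 ≈ 0.538 and coupling = 1 − 9/28 ≈ 0.679.

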