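# Methods

This note documents the models and procedures `mitoquant` implements,
the defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical conventions that matter at boundaries.

## Mitochondrial morphometry

The morphometry pipeline operationalizes the standard FIJI-style
punctate-stain workflow for tissue sections:

1. **z-projection.** Each channel is collapsed across slices; the default
   reduction is maximum intensity, the usual choice for punctate
   mitochondrial signal (a mean projection is available). Slice geometry
   follows typical slide-scanner acquisition: 5 slices at 1 µm spacing.
2. **Cell ROIs.** The marker channel (GFAP or MAP2) is projected and
   auto-thresholded; all marker-positive regions in a field are pooled
   into one ROI union. Densities are therefore *per-field* statistics
   (count over total marker-positive area), not per-cell assignments.
   An empty marker mask flags the field "no cells" and the density is
   reported missing, never 0/0.
3. **Background subtraction.** The target (TOMM20) projection has a
   disk-footprint median filter (radius 4 px, reflect padding)
   subtracted, clipped at zero. A median filter estimates background
   correctly only where features occupy less than half its footprint: a
   radius-4 disk covers 49 px, so objects larger than ~24 px have their
   interior counted as "background" and suppressed (a 25-px disk loses
   its 5 central pixels; much larger blobs survive only as rims). This is
   an intrinsic property of median-based background subtraction, not an
   implementation artifact; the sampling defaults below keep programmed
   particles out of that regime.
4. **Auto-threshold.** Default is the isodata (iterative intermeans)
   method; Otsu is offered as an alternative and the chosen threshold is
   recorded in the result metadata. One convention matters: on
   background-subtracted images the histogram carries a dominant
   clipped-at-zero bin, and the isodata criterion can then admit several
   fixed points (one separating zeros from noise, one separating signal
   from everything else). `auto_threshold` uses the **largest** fixed
   point. On clean two-level histograms there is a single fixed point,
   so the convention is inert there. Foreground is strictly `> t`.
5. **Watershed.** Euclidean-distance-transform watershed with
   local-maximum-plateau seeds: a pixel seeds iff its distance value
   equals the maximum within a 2-px disk, and connected plateaus merge
   into one seed. A single blob of any shape (including rims left by the
   median filter) yields one seed and is never oversplit; two touching
   convex blobs keep separate plateaus and are split at the distance-map
   saddle. Separation lines are labeled 0 and excluded from pixel counts.
   Labeling is 8-connected; coordinates are 0-based row-major.
6. **Measurement and filtering.** Particle area is pixel count ×
   pixel_size²; particles with area **< 0.4 µm²** are discarded as pixel
   noise (the boundary is strict: 0.4 µm² survives), and a particle is
   assigned to the ROI iff its centroid lies inside (the thresholded
   target mask is restricted to the ROI before watershed). Raising the
   minimum area can only decrease the count (tested property).

Summaries per field: `n`, density `n / cell area` (per mm²), mean and
sample-SD (ddof = 1) of particle areas, and a size histogram. The field →
section → animal → group hierarchy is preserved in tidy tables for the
statistics layer.

## Fractional marker area

For each manually annotated cell (polygon or mask; GeoJSON polygons with
a `cell_type` property are accepted), the statistic is the fraction of
the cell's pixels whose target intensity is **strictly above** a
threshold `t = mean(3 background measurements) × SNR`. The SNR is an
explicit per-image input (default 3.0) because no calibrated definition
is universal across rigs; an optional estimator (mean of the top-decile
annotated pixels ÷ background mean) is provided and always reported when
used. The statistic is invariant under common intensity rescaling of
image and background (tested), and non-increasing in the threshold.
Regions with fewer than 15 annotated cells of the relevant type trigger
a warning (the usual region-selection rule), not an error. Group
summaries report mean ± s.e.m. and the full pairwise mean-ratio matrix.

## SUIT respirometry

The trace is O₂ concentration (nmol/mL) against time with an injection
event list in protocol order: digitonin (permeabilization), pyruvate +
malate (CI leak), ADP (CI OXPHOS), cytochrome c (membrane QC), succinate
(CI+CII OXPHOS), rotenone (CII OXPHOS), FCCP (uncoupled; may repeat as
titration steps — the maximum step flow is taken).

Each state's measurement window runs from its defining injection to the
next injection present in the record (so partial protocols yield missing
later states rather than errors); Ce is measured before the first
injection, and CI_L from the post-malate segment, when both substrates
are present. The flow is −(least-squares slope) over the **trailing 50 %**
of the window (configurable) — the leading part of a segment is treated
as mixing/equilibration time — scaled to pmol·s⁻¹ per 10⁶ cells. With
the trace as a concentration and the cell count as a chamber density
(10⁶ cells/mL), the chamber volume cancels in that normalization; it is
still recorded for provenance. O₂ consumption is reported positive, and
a fit needs ≥ 5 samples.

**Cytochrome-c rule.** A sample is excluded iff the post-cytochrome-c
flow exceeds the CI_P flow by *more than* 10 % (exactly +10 % passes);
a zero CI_P baseline fails with an explicit reason.

**Derived metrics.** The relative contributions divide by the *measured*
combined state CI+CII_P, not the arithmetic sum CI_P + CII_P: the two
complexes' capacities are not additive, so the measured combined flow is
normally below the sum and the two relative contributions can jointly
exceed 1 — which is exactly the observed pattern in both cell types of
the motivating dataset. A `literal_sum` flag computes the arithmetic-sum
variant (which forces rel CI + rel CII = 1) for comparison. Coupling
efficiency 1 − CI_L/CI_P is invariant under common rescaling of all
flows. Any metric whose inputs are missing or whose denominator is zero
is reported missing with a reason, never raised mid-batch.

## Expression comparison

Genes silent in both groups (TPM = 0 in each) are removed before
anything else. The signed fold change is `+b/a` when `b ≥ a` and `-a/b`
otherwise — magnitude always ≥ 1, sign pointing at the higher group;
swapping groups flips the sign (tested). Genes expressed in exactly one
group get ±inf with an `infinite_fold` flag by default; an optional
pseudocount replaces that convention. P-values (inputs from an upstream
DE engine, not recomputed) are adjusted by Benjamini–Hochberg step-up
(delegated to `statsmodels.multipletests`; a brute-force step-up oracle
verifies it in the tests), and the DE call is strict: FDR < 0.05.
Against the curated electron-transport-chain reference table bundled
with the package, the signed TPM ratio reproduces the upstream engine's
printed fold changes within 1 % for the four well-expressed marker genes
(SDHA, NDUFA9, SDHB, NDUFS1) and within 3 % table-wide.

## Statistics layer

* **Gated one-sided t-test** (fractional areas): Shapiro–Wilk per sample
  and Levene across samples are run and recorded as gates at α = 0.05;
  the test itself is the pooled-variance two-sample t-test with a
  declared direction — the direction is a required argument because the
  biological expectation fixes it per comparison, and the code cannot
  guess it. Two constant equal samples give p = 1 by convention. Null
  calibration (two N(0,1) samples, n = 20, 10,000 simulations) keeps the
  type-I error within [0.04, 0.06] (tested).
* **ANOVA + Tukey HSD** (respirometry): one-way ANOVA with
  studentized-range pairwise p-values. With two groups Tukey collapses to
  the two-sided pooled t-test via q = √2·|t| (tested identity).
  Zero within-group variance is reported as a degenerate result, not an
  exception.
* **Group-mean models** (morphometry): fixed-effects GLM over
  group × cell-type cells — Poisson with log link and a log(cell-area)
  offset for counts (lsmeans are log-densities), Gamma with log link for
  sizes (lsmeans back-transform by `exp` to mean sizes), Gaussian
  identity otherwise. The section-within-animal nesting is honored by
  aggregating images to sections before fitting and, when requested,
  resampling animals with replacement within each group (cluster
  bootstrap, default 1,000 replicates, seeded) for contrast standard
  errors; without the bootstrap the GLM covariance is used. This is a
  deliberate replacement for a nested-random-effects mixed model: lsmean
  point estimates coincide in balanced designs, and the bootstrap
  carries the animal-level variance inflation, but the per-coefficient
  standard errors of a true mixed fit are not reproduced. Pairwise
  contrasts are differences of lsmeans (exactly — tested against the
  bundled published tables, every printed contrast equals the difference
  of its two printed lsmeans within table rounding) with a Tukey-style
  studentized-range adjustment at asymptotic df.

## Synthetic data: what it emulates, and what it does not

* **Images.** 3-channel z-stacks (marker / target / nuclear) over a
  known integer-label cell mask. Mitochondria are filled discrete disks
  of exact pixel count (offsets ranked by distance, ties in raster
  order), so the recorded truth area is exactly pixel count ×
  pixel_size²; each particle spans a contiguous run of slices (default
  all). Noise is additive Gaussian clipped at zero (Poisson shot noise
  behind a flag); background and amplitude default to 100 and 1000 a.u.
  — roughly a 10:1 stain-to-autofluorescence ratio, typical of a
  well-exposed section; noise defaults to 0 so programmed truth is exact,
  with recovery studies run at SD = 10 % of amplitude. The recovery
  default calibration is 0.1 µm²/px (pixel size √0.1 ≈ 0.316 µm, e.g. a
  2×-binned 40× slide-scanner scan): it keeps the programmed 0.5–2.0 µm²
  size range below half the radius-4 median footprint (the transparent
  regime of step 3 above) and makes 0.3 / 0.4 µm² exact pixel counts
  (3 / 4 px) so the noise-cutoff boundary is representable exactly.
  Not emulated: PSF/optics blur, cell-shape realism, 3D structure,
  spatially varying background. Passing tests therefore demonstrate the
  pipeline's arithmetic and its robustness to pixel noise, not
  performance under optical blur or anisotropy.
* **Respirometry.** Piecewise-linear O₂ traces whose per-segment slope
  encodes the programmed state flow at the chamber's cell density, with
  optional Gaussian noise and optional step artifacts at injections
  (re-oxygenation bumps; they do not bias the trailing-window slopes).
  Sensor drift and diffusion into the chamber are not modeled.
* **Expression tables.** Deterministic tables honoring programmed signed
  folds and p-values, including silent genes to exercise the TPM > 0
  filter.

Identical spec + seed reproduce every generator bit-for-bit.

## Numerical conventions and edge cases

* Strict inequalities at every stated boundary: particle exclusion
  (< 0.4 µm²), positive-pixel test (> threshold), DE call (FDR < 0.05),
  cytochrome-c exclusion (> +10 %).
* Thresholding a constant image is undefined: empty mask plus warning.
* Zero cell area, zero CI_P, empty design cells and missing injections
  all produce flagged missing values with reasons, not exceptions, so
  batch runs degrade gracefully.
* TIFF export is 16-bit (clipped/rounded); the in-memory pipeline is
  float64 throughout. Calibration travels in a YAML sidecar.
* Problem sizes in the test suite (20 synthetic 1024² fields for image
  recovery, 10,000 null simulations for t-test calibration, 800 GLM
  simulations for lsmean coverage) were chosen as the smallest sizes at
  which the stated tolerances are statistically meaningful.

## Known limitations

* No bit-parity with FIJI/ImageJ internals (histogram binning, watershed
  tie-breaks); the pipeline reproduces the method, not the binary.
* Per-cell (as opposed to per-field) mitochondrial assignment, 3D
  volumes and network topology are out of scope.
* The mixed-model approximation above reports honest bootstrap contrast
  uncertainty but not the exact standard errors or Z-ratios a
  Laplace-approximated nested random-effects fit would give.
* Group-level respirometry values of any particular real dataset require
  that dataset's raw traces; the package verifies its extraction and
  metric arithmetic on ground-truthed synthetic traces instead.
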