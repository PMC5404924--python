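# Methods

This note documents the models, defaults and numerical choices behind
`rgcquant`, and what the synthetic validation does and does not show.

## Assay model

The package quantifies RGC survival after optic nerve crush from
two-channel whole-mount retina scans.  Its unit of inference is one
animal: the double-positive (γ-synuclein⁺/TUJ-1⁺) cell count of the
crushed retina, normalized to the uncrushed retina of the same animal,
expressed in percent.  Group effects are assessed on these per-animal
percentages with a two-tailed pooled-variance Student t-test (data
reported as mean ± SEM), optionally after removing at most one Grubbs
outlier per group at α = 0.05 (applied once, not iteratively).  An
ordinal 0–5 axon-degeneration score, produced by blinded manual
scoring, is handled as an imported data column and compared with the
same machinery.

## Stages, parameters, defaults

### Tissue mask

Otsu's threshold applied to the sum of the two channels after
winsorizing at the 80th intensity percentile, then closing with a 5 µm
disk, hole filling, and selection of the largest 8-connected
component.  The winsorization is load-bearing: fluorescence histograms
are background / tissue / bright-structure trimodal, and plain Otsu
flips to splitting tissue-from-cells once cells and bundles contribute
enough variance.  Clipping at the 80th percentile collapses the bright
tail while leaving the background/tissue step intact; it assumes
bright structures cover < ~20 % of the field and bare slide < ~80 %,
which holds for whole-mount scans.  (A log transform was considered
and rejected: with additive noise clipped at zero it creates a
zero-intensity spike that becomes its own Otsu class.)

### Sampling band

Pixels whose exact Euclidean distance to the nearest background pixel,
in µm, lies in [150, 650] (offset 150 µm, thickness 500 µm; both
configurable).  The protocol's "approximately" is resolved as exact
inclusive bounds for reproducibility.  The distance is measured to all
tissue boundary pixels, including incision edges — whether the
original implementation measured only from the outer rim is unknown;
this choice is documented rather than guessed.  Tissue touching the
image border is treated as interior (the transform sees no background
there).  An empty band warns and returns empty rather than raising:
downstream stages handle zero detections.

### Nucleus detection

Fast radial symmetry transform, bright polarity, on the γ-synuclein
channel.  Per radius *n* (px): gradients via central differences;
pixels with gradient magnitude above 0.05 × max vote at
p + round(n·ĝ); the orientation projection O is saturated at κ (8 for
n = 1, 9.9 otherwise) and the response is
(|Õ|/κ)^α · |M|/(κ·m̄) with α = 2 and m̄ the mean above-threshold
gradient magnitude, smoothed with a Gaussian of σ = n/4.  The aggregate
map is the mean over radii; the best radius per pixel is recorded.
Normalizing by m̄ makes the response exactly invariant under linear
intensity scaling, so the absolute score threshold transfers across
images and acquisition gain.  Votes landing outside the image are
discarded.

Detections are local maxima (8-neighborhood) inside the band with
score ≥ threshold, accepted greedily in descending score order under a
minimum center separation, ties broken by (row, col).  Defaults
matched to the synthetic study at 1 µm/px: radii {3, 4, 5} µm,
score threshold 0.10, separation 8 µm.  The original study's radii,
α and threshold are not reported anywhere; these are explicit
configuration, not a reconstruction.

### Double-label classification

TUJ-1 positivity is defined once per retina: Otsu's threshold over the
band pixels of the TUJ-1 channel (256 range-adaptive bins; threshold
returned as the upper edge of the argmax split, ties toward the lower
threshold; pixels strictly above are positive).  A per-cell threshold
would make the 50 % rule non-comparable across cells.

Each detection gets a ring at its nucleus border: pixels with
inner_radius ≤ d < inner_radius + 2 µm from the (sub-pixel) center.
The cell is positive iff strictly more than 50 % of its considered
ring pixels are TUJ-1-positive.  Ring width 2 µm is a package default
(unreported in the original protocol) and configurable.

Axon bundles: the binarized TUJ-1 channel is opened with a 2.5 µm
disk — erasing the ~2 µm somatic rings while preserving ≥ ~6 µm-wide
bundles — and connected components with area ≥ 500 µm² are taken as
bundles, then dilated by one ring width to protect adjacent rings.  An
elongation (major/minor axis) gate exists but defaults to off: bundles
that cross, or radiate from a common hub as retinal bundles do, merge
into components whose moment-based axis ratio approaches 1, so any
strict elongation requirement silently disables bundle masking
(observed as amacrine false positives).  Ring pixels inside the bundle
mask leave the denominator; when more than half the ring is
bundle-covered the cell is flagged excluded, its fraction is NaN, and
it counts in `n_detected` but never in `n_double_positive`.

### Survival normalization

`normalize_survival` offers `count` (raw double-positive counts),
`density` (counts divided by band area), and `auto` (density when band
areas differ by > 10 %).  The *pipeline* default is density over the
**scoreable** band area (band minus the dilated bundle mask): bundle
coverage removes a random ~5–15 % of the band per retina, and raw-count
ratios inherit that variance, while densities over the scoreable area
are unbiased by it.  With identical scoreable areas the two reduce to
the same number.  Values above 100 % are possible and preserved.

### Statistics

Pooled (not Welch) two-tailed t-test, df = n₁ + n₂ − 2, delegated to
`scipy.stats.ttest_ind(equal_var=True)`.  Zero pooled variance returns
p = 1 when the means are equal and raises otherwise (the limit "p → 0"
for separated constant groups is not silently fabricated).  Grubbs'
critical value uses the two-sided t-form
G = (n−1)/√n · √(t²/(n−2+t²)), t = t₍α/(2n), n−2₎.

## Synthetic retina generator

The generator renders the specimen the pipeline expects, at
configurable scale, with exact ground truth:

* **Tissue**: a disk (default radius 92 % of the half-image) with
  `n_leaves` = 4 parallel-sided radial incisions (width 40 µm,
  reaching 60 % of the radius inward, semicircular inner caps).  The
  analytic mask is regularized by a closing at 5 µm — the same scale
  the pipeline's mask recovery uses; closing is idempotent, so the
  noiseless round-trip recovers the mask exactly.  Caps are rounded
  (20 µm curvature radius) for the same reason.
* **Cells**: nucleus disks (radius 4 ± 0.4 µm, truncated normal) in
  channel 1 for both classes; RGCs additionally get a TUJ-1 ring at
  the nucleus border (rendered 1 px wider on each side than the
  nominal annulus so every classifier ring pixel sees full intensity
  despite anti-aliasing).  Placement is rejection sampling, by default
  inside the sampling band (where the assay counts), with minimum
  center spacing 2 × nucleus radius (reference scenes use 16 µm, see
  below) and an attempt cap that raises an explicit packing error.
* **Bundles**: bright stripes (default 10 µm wide) along random
  chords, clipped to tissue, in channel 2.
* **Intensities**: background 100, cells and rings 600, bundles 450
  (arbitrary units rendered to 16-bit TIFF).
* **Degradations**: multiplicative linear illumination ramp (default
  0.2 across the field), additive Gaussian noise (default σ = 20),
  optional Poisson shot component (off by default).  At these defaults
  the faintest structure that must be segmented — the tissue step over
  bare slide — has SNR 5; cells have SNR 25.
* **Pairs**: the uncrushed retina carries `n_rgc` RGCs, the crushed
  one an independent draw of `round(survival_fraction × n_rgc)`;
  amacrine counts are identical in both, as amacrine cells are not
  lost to the injury.  All randomness flows from a single seed through
  spawned substreams; identical spec ⇒ bit-identical output.

### Reference study conditions

`rgcquant.presets` freezes the simulation study: 1400 × 1400 px at
1 µm/px, tissue radius 650 µm, 150 RGCs + 40 amacrine cells placed in
the band at ≥ 16 µm spacing, 3 bundles.  The survival study runs
planted fractions {0.25, 0.5, 0.75, 1.0} × 5 animals (one crushed +
one uncrushed retina each).  These sizes keep a full study at around
two minutes on one CPU while leaving ≥ 130 in-band RGCs per retina, so
the counting statistics, not the scene size, dominate the error.  The
16 µm spacing floor is a model constraint, not merely a convenience:
the rendered ring reaches ~7.5 µm from the center, and below ~15 µm
spacing neighbouring rings chain into elongated structures that the
bundle filter correctly — but unhelpfully — masks out.

### What the simulation does not emulate

Real vasculature and texture, z-structure, staining heterogeneity
between animals, cell shape irregularity, true RGC densities
(~2000–3000 /mm² in mouse; the synthetic density is far lower because
of the ring-chaining constraint above), and bundle branching
morphology.  Passing the recovery tests therefore demonstrates the
correctness and calibration of the algorithmic chain under controlled
conditions, not field performance on real scans; the detector's
parameters (radii, score threshold) must be re-tuned per real
acquisition setting.

## Numerical conventions

Coordinates are 0-based (row, col); physical parameters are µm,
converted once per image via the pixel size.  Local-maximum ties break
lexicographically.  Otsu ties break toward the lower threshold.  The
round-half-even convention of NumPy applies wherever fractions of
cells are rounded (`round(0.72 × 200) = 144`).  Images are processed
as float64; TIFF output is 16-bit.

## Known limitations

* Tissue masking assumes the trimodal histogram structure described
  above; fields dominated by bare slide (> ~80 %) defeat the
  winsorization heuristic.
* The band measures distance from *all* boundary pixels including
  incisions; protocols that measured only from the outer rim will
  report slightly different band areas on deeply incised mounts.
* Bundle masking is geometric (width/area), not appearance-based; very
  wide non-bundle artifacts (tears, folds) would be masked as bundles.
* Survival normalization presumes comparable acquisition between the
  two retinas of an animal; the density option corrects area, not
  staining efficiency.
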