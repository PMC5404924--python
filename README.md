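# rgcquant

Automated quantification of retinal ganglion cell (RGC) survival in
two-channel fluorescence scans of whole-mount retinas.

## The problem

After optic nerve crush (ONC), RGCs — the projection neurons whose
axons form the optic nerve — die over the following two weeks, and
neuroprotection studies quantify how many survive.  Counting RGCs in a
whole-mount retina by a single marker is confounded: γ-synuclein labels
both RGCs and displaced amacrine cells, which are not lost after crush.
The assay implemented here resolves this with double labeling: a cell
is an RGC only if its γ-synuclein⁺ nucleus is surrounded by
TUJ-1 (βIII-tubulin) staining.

## The method

For each scanned retina (channel 1 = γ-synuclein, channel 2 = TUJ-1,
pixel size in µm supplied by configuration):

1. **Tissue mask** — Otsu threshold of the winsorized channel sum,
   morphological closing, hole filling, largest connected component.
2. **Sampling band** — the peripheral region of pixels whose Euclidean
   distance *d* to the tissue edge satisfies 150 µm ≤ *d* ≤ 650 µm
   (offset and thickness configurable); cells are counted only here.
3. **Nucleus detection** — fast radial symmetry transform of the
   γ-synuclein channel: pixels with strong gradients vote *r* pixels
   along their gradient direction; the per-radius response
   (Õ/κ)^α · M/(κ·m̄) is smoothed and averaged over candidate radii
   *r* ∈ {3, 4, 5} µm, and nuclei are band-restricted local maxima
   with non-maximum suppression.
4. **Double-label call** — a ring of width 2 µm centered on the
   nucleus border is scored against the Otsu threshold of the TUJ-1
   channel (computed once per retina over the band); the cell is
   RGC⁺ iff **strictly more than 50 %** of the ring pixels are
   TUJ-1-positive.  Large contiguous TUJ-1 regions (axon bundles,
   isolated by a morphological opening plus area filter) are removed
   from the ring denominator; a cell whose ring is majority-bundle is
   excluded from scoring.
5. **Survival** — per animal, the crushed retina's double-positive
   count (as a density over the scoreable band area) is normalized to
   the same animal's uncrushed retina: survival % = 100 · crushed /
   uncrushed.  Groups are compared with a two-tailed pooled Student
   t-test (mean ± SEM); single outliers can be screened with Grubbs'
   test at α = 0.05.

Because no raw scans of this assay are publicly available, the package
ships a first-class synthetic generator (`rgcquant.synthetic`) that
renders whole-mount retinas — a tissue disk with four radial incisions,
double-positive RGCs, γ-synuclein⁺/TUJ-1⁻ amacrine confounders,
elongated axon bundles, illumination gradients and noise — together
with an exact ground-truth cell table, so every stage is testable
against known truth.

## Worked example

```python
import rgcquant as rq
from rgcquant.presets import reference_config, survival_study_spec
from rgcquant.pipeline import quantify_image

# one synthetic animal: crushed retina planted at 72 % RGC survival
spec = survival_study_spec(survival_fraction=0.72, seed=42)
(crushed_img, _, _), (uncrushed_img, _, _) = rq.generate_pair(spec)

config = reference_config()
crushed = quantify_image(crushed_img, config, "mouse1", "crushed")
uncrushed = quantify_image(uncrushed_img, config, "mouse1", "uncrushed")
result = rq.normalize_survival(crushed.count, uncrushed.count,
                               "mouse1", method="density")

print(f"crushed:   {crushed.count.n_double_positive} double-positive RGCs "
      f"({crushed.count.n_detected} nuclei detected)")
print(f"uncrushed: {uncrushed.count.n_double_positive} double-positive RGCs "
      f"({uncrushed.count.n_detected} nuclei detected)")
print(f"estimated survival: {result.survival_percent:.1f}%  (planted: 72.0%)")
```

prints

```
crushed:   101 double-positive RGCs (148 nuclei detected)
uncrushed: 135 double-positive RGCs (190 nuclei detected)
estimated survival: 74.5%  (planted: 72.0%)
```

The uncrushed retina carries 150 planted RGCs plus 40 amacrine cells;
190 nuclei are detected in the sampling band, of which 135 pass the
double-label rule (the remainder are amacrine cells or bundle-excluded).
The density-normalized ratio recovers the planted 72 % survival within
a few percentage points.

The same pipeline is available from the shell:

```bash
rgcquant simulate --outdir sim --seed 1
rgcquant quantify --synthetic-spec sim/spec.yaml --outdir run --seed 1
rgcquant compare --survival-csv cohort/survival.csv
```

`rgcquant quantify --input-tiff crushed c.tif --input-tiff uncrushed u.tif
--pixel-size-um 0.46 --outdir run` quantifies real two-channel TIFFs
(channel order: synuclein, TUJ-1).

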