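# petoverlap

Phantom-driven evaluation of how PET functional-volume segmentation methods
bias the estimated spatial overlap between a pre-treatment high-uptake tumour
sub-volume (**V1**) and the post-treatment residual uptake (**V2**).

## The problem

Dose-painting strategies in radiotherapy assume that the residual or relapsing
uptake seen on a post-treatment FDG-PET scan coincides with the high-uptake
sub-volume of the pre-treatment scan. Testing that hypothesis requires
segmenting both volumes and quantifying their spatial agreement — but fixed
%SUVmax thresholds, the most common delineation choice, are known to be
unreliable, especially for small, low-contrast residuals. Biased segmentations
produce biased overlap estimates, and can even report a substantial overlap
where none exists.

This package reproduces that analysis in a fully controlled setting: a
synthetic phantom with known ground truth, rendered through an analytic PET
image-formation model, segmented with the full threshold family and with a
fuzzy locally adaptive Bayesian (FLAB-style) mixture method, and scored with
the four standard overlap metrics.

## The quantities

For binary masks V1 and V2 with intersection I:

```
Dice = 2|I| / (|V1| + |V2|)      OF = |I| / min(|V1|, |V2|)
X    = |I| / |V1|                Y  = |I| / |V2|
```

(OF = max(X, Y) and Dice = 2XY/(X+Y); Jaccard is computed but is redundant
with Dice for ranking.) Against ground truth the package also reports an
overlap **accuracy**: the mean of positive predictive value and sensitivity of
the estimated overlap region relative to the true overlap region.

The segmentation methods are:

- `threshold_segment`: every ROI voxel at or above xx% of the ROI maximum
  (xx in 30…90 for V1; 40 or 90 for V2), the combinations denoted `xxyy`;
- `flab_segment`: a spatially regularized Gaussian mixture with fuzzy
  transition levels — 3 classes on the pre-treatment image (background,
  tumour, high-uptake sub-volume), 2 classes on the post-treatment image.

## Worked example

```python
import petoverlap as po

config = po.PhantomConfig()                      # 48^3 grid, 4 mm voxels
gt = po.build_ground_truth(config)               # tumour, V1 (~20%), V2
for name in ("high", "low", "none"):
    placed = po.place_residual(gt, po.canonical_offset(name))
    rep = po.overlap_metrics(placed.v1_mask, placed.v2_mask, config.spacing)
    print(f"{name:>4}: Dice={rep.dice:.3f} OF={rep.of:.3f} "
          f"X={rep.x:.3f} Y={rep.y:.3f}  mean={rep.mean4:.3f}")
```

prints

```
high: Dice=0.766 OF=0.778 X=0.755 Y=0.778  mean=0.770
 low: Dice=0.348 OF=0.353 X=0.343 Y=0.353  mean=0.349
none: Dice=0.000 OF=0.000 X=0.000 Y=0.000  mean=0.000
```

— the three packaged configurations: substantial (~0.77), small (~0.35) and
non-existent true overlap. Segmenting the rendered images
(`examples/02_segmentation_methods.py`) shows the threshold failure mode on
the 2:1-contrast residual:

```
V2  T40:  1029 voxels =   65.9 cm^3     (over-segmented)
V2 FLAB:   408 voxels =   26.1 cm^3
V2  T90:     4 voxels =    0.3 cm^3     (under-segmented)
V2   GT:   388 voxels =   24.8 cm^3
```

and `examples/04_simulated_example_report.py` prints the full wide comparison
table (all threshold combinations vs the Bayesian pair vs ground truth, with
percent deviations and overlap accuracies). On the disjoint configuration the
Bayesian pair reports exactly zero overlap while loose threshold pairs report
a spurious one. The `examples/` directory has one short script per capability
(phantom, segmentation, registration, the wide report, a synthetic cohort);
the same functionality is scriptable through the thin `petoverlap` CLI
(`simulate`, `segment`, `register`, `overlap`, `cohort`, `report`).

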