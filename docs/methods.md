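# Methods

## Phantom and ground truth

The synthetic study object is a single tumour on a 48×48×48 grid of
4×4×4 mm voxels (the grid of a typical clinical PET reconstruction). The
tumour is the best-scoring connected component of a smoothed Gaussian random
field with a radial compactness penalty — an irregular blob rather than a
sphere, so that thresholds and the mixture method face a realistic boundary.
Its default size is 2,000 voxels (128 cm³). That scale is deliberately larger
than a typical clinical lesion: with ~400 voxels in the sub-volume, the
achievable overlap values under integer-voxel translation are dense enough to
realise the target configurations precisely, and the segmentation ROIs are
comfortably above the stability threshold of the mixture estimation. All
geometry is deterministic per seed (default seed 7).

The high-uptake sub-volume **V1** is grown inside the tumour from a
boundary-biased seed (the tumour voxel furthest along +x) until it holds 20%
of the tumour. The residual **V2** copies V1's shape contracted towards V1's
centroid to 97% of its size (so |V2|/|V1| ≈ 0.97, matching the near-equal
sizes implied by the reference ground-truth row where X ≈ Y), and is
translated on the voxel lattice to realise a configuration.

`solve_offset` searches all integer translations within a radius (intersection
counts for every offset from a single FFT cross-correlation; ties broken by
offset length, then lexicographically). The three packaged offsets were chosen
once with this search:

| configuration | offset (voxels) | mean of Dice/OF/X/Y |
|---|---|---|
| high | (1, 0, 0) | 0.7695 |
| low | (2, −2, −2) | 0.3491 |
| none | (−9, −2, 0) | 0 exactly |

The "none" offset displaces V2 across the tumour bed rather than into empty
background: the disjoint residual still lies over the original tumour, as a
geographically missed relapse would, which is precisely the geometry in which
loose thresholds report a spurious overlap.

## Image formation

Rendering is analytic: piecewise-constant activity (background 1.0) →
isotropic Gaussian PSF (default FWHM 5 mm) → voxel-wise multiplicative
Gaussian noise (default CV 0.10, seeded) with negatives clipped. This replaces
a full Monte-Carlo simulation/reconstruction chain; it preserves the phenomena
under study — blur, partial-volume effect, noise — but not reconstruction
artefacts, scatter or attenuation effects, so reference segmentation values
are directional rather than bit-exact targets for this phantom.

"Measured contrast" is defined as the ratio of region means, with the
background region excluding a 2-voxel dilation ring around the uptake to avoid
spill-in. Activities are calibrated by a fixed-point iteration (≤20 rounds,
tolerance 1e−6) so that the *blurred noiseless* image measures 3:1
(tumour:background) and 6:1 (V1:background) on PET1 and 2:1 (V2:background)
on PET2. With the PSF disabled the calibration leaves the nominal ratios
untouched, so the unblurred maps measure exactly 6:1 and 2:1.

## Segmentation

`threshold_segment` keeps every ROI voxel at or above the stated fraction of
the ROI maximum (inclusive comparison; the maximum voxel, ties broken by
lowest linear index, is always a member). No hole-filling or
connected-component post-processing is applied to either method, keeping the
comparison symmetric.

`flab_segment` is a fuzzy, spatially regularized Gaussian mixture:

- *n* hard classes with Gaussian likelihoods, plus (default) two fuzzy levels
  between each adjacent pair whose means/variances linearly interpolate the
  class parameters at α = 1/3, 2/3;
- a Potts-style local prior: each label's log-posterior gains β (default 1.0)
  times the sum of its 6-neighbours' posterior mass (mean-field approximation);
  there are no global mixing weights — a free global weight feeds back into
  the mean-field term and can collapse a class;
- EM-style estimation: posterior update, then class means/variances from
  posteriors with fuzzy mass split between adjacent classes by its
  interpolation weights; convergence when all class means change by <1e−4
  relatively, cap 100 iterations;
- hard masks by maximum aggregated class membership, so a fuzzy voxel lands in
  the adjacent class of higher posterior; classes reported by ascending mean.

Initialisation is deterministic and contrast-adaptive: 2-class means at 20%
and 80% of the ROI intensity *range* (quantiles fail here — background
dominates a bounding-box ROI, so a high intensity quantile can still sit below
the uptake mode). The 3-class fit is initialised hierarchically: a fast
2-class fit splits background from uptake, then the third class starts near
the maximum (95% of the range); this anchors the middle class to the
bulk-tumour mode, which single-shot initialisations repeatedly lost. Initial
variances are floored at (0.05 × range)² so a misplaced initial mean cannot
zero a class's likelihood before the first update. An empty class collapses
the fit to fewer classes with a warning.

With β = 0 and fuzzy levels disabled the loop is exactly EM for an
equal-weight Gaussian mixture; the test suite checks the class means against
an independent mixture fit to <1%.

## Registration

`register_rigid` wraps a standard Mattes mutual-information registration
(32 bins, all voxels — no random sampling, so the procedure is deterministic;
Powell-style optimiser) initialised by aligning intensity centres of mass.
Translation-only by default; rotation is available but off, since synthetic
pairs share axes. An optional fixed-image mask (`uptake_focus_mask`) restricts
the metric to the neighbourhood of the dominant uptake — the synthetic
analogue of registering only the body region containing the tumour, and the
cure for the classic failure mode where shrinking image overlap inflates MI on
background-dominated images. Resampling offers nearest (masks), linear, and
Lanczos-windowed sinc; sinc is used for quantitative images because repeated
linear interpolation measurably inflates subsequent uptake-volume estimates.

## Cohort emulation

`synth_cohort` generates independent cases: fresh tumour geometry, a uniform
random true-overlap target in [0, 0.9] realised by `solve_offset`, a residual
size ratio uniform in [0.8, 1.2] (so some estimated V2 exceed V1), and a
random rigid misalignment of the post-treatment scan. Two site profiles differ
in misalignment magnitude (SD 2 mm vs 6 mm) and in how hard the registration
problem is (structural noise 5% vs 15%), emulating the oesophageal vs
head-and-neck contrast in registration difficulty. Alignment is computed on a
structural image pair (the tumour bed at 2:1 contrast, identical structure at
both time points, independent noise) and applied to the PET — the analogue of
CT-driven registration; registering the PET pair directly would snap the
displaced residual back onto the tumour and destroy the designed overlap. The
misaligned scan is "acquired" misaligned: the noiseless image is moved
continuously, then noise is added, so it is degraded once, like a real scan.

Per case the full grid of 15 combinations (7 × 2 thresholds + the Bayesian
pair) is computed; overlap analysis is gated on strictly V2 < V1 under the
reference method (FLAB, configurable). Summaries report mean, sample SD (n−1)
and median; distribution comparisons use the two-sided Mann-Whitney rank test
(exact enumeration when both samples have ≤8 observations without ties,
tie-corrected normal approximation otherwise; all-tied samples give p = 1),
significance at p < 0.01 with no multiplicity correction.

## What the phantom does and does not show

The generator emulates contrast, blur, partial volume, noise texture and
inter-scan misalignment. It does not emulate reconstruction artefacts,
heterogeneous background anatomy, tracer-kinetic variability, organ motion or
deformation. Passing tests therefore demonstrate the *mechanisms* of
threshold-induced overlap bias and their correction by a statistically
grounded segmentation, not clinical performance figures. The Bayesian V2
estimate carries a small positive volume bias (~+5% unresampled, ~+10% after
realignment resampling), which lowers the gated fraction of a cohort below
the ~50% seen clinically — a consequence of multiplicative noise (larger
variance in the uptake class pulls the decision boundary outwards) noted here
so that cohort-level numbers are read correctly.

## Numerical details and edge cases

- Masks are dense boolean volumes, 0-based indices, ≥3-voxel border margins
  enforced; volumes in cm³ via the spacing product.
- `overlap_metrics` requires non-empty masks; overlap accuracy is undefined
  (None / "N/A") when the true overlap is empty, and PPV is defined as 0 for
  an empty estimated overlap when the true one is non-empty.
- The accuracy construction compares the *overlap regions* (V1∩V2 estimated
  vs true), not per-volume PPV/SE averaged over V1 and V2 — the definition is
  ambiguous in the overlap-analysis literature; this reading is declared here.
- Thresholds use the single maximum voxel as the reference (no peak
  averaging).
- The wide report prints values to 3 decimals with percent deviation from the
  ground-truth column in parentheses (omitted where the reference is 0).
- End-to-end determinism: every random step consumes a named seed; re-running
  any pipeline stage with the same configuration reproduces outputs exactly.
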