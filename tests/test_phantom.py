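"""Ground-truth construction, residual placement, offset search and the
analytic image-formation chain."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import petoverlap as po


def _connected(mask):
    _, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    return n == 1


# ---------------------------------------------------------------- ground truth

def test_ground_truth_structure(default_gt):
    gt = default_gt
    assert gt.v1_mask.sum() / gt.tumour_mask.sum() == pytest.approx(0.20, abs=0.05)
    assert not np.any(gt.v1_mask & ~gt.tumour_mask)  # subset invariant
    for mask in (gt.tumour_mask, gt.v1_mask, gt.v2_mask):
        assert _connected(mask)
        idx = np.argwhere(mask)
        assert idx.min() >= 3
        assert (idx.max(axis=0) <= np.array(gt.grid.shape) - 4).all()
    assert 0.8 <= gt.v2_mask.sum() / gt.v1_mask.sum() <= 1.2


def test_ground_truth_deterministic(default_config, default_gt):
    again = po.build_ground_truth(default_config)
    for a, b in ((again.tumour_mask, default_gt.tumour_mask),
                 (again.v1_mask, default_gt.v1_mask),
                 (again.v2_mask, default_gt.v2_mask)):
        assert np.array_equal(a, b)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        po.PhantomConfig(v1_fraction=0.6)
    with pytest.raises(ValueError):
        po.PhantomConfig(contrast_tumour_bg=0.5)
    with pytest.raises(ValueError):
        po.PhantomConfig(noise_cv=-0.1)
    with pytest.raises(ValueError):
        po.build_ground_truth(po.PhantomConfig(shape=(16, 16, 16)))  # cannot fit


# ------------------------------------------------------------- place_residual

def test_place_residual_identity_and_conservation(default_gt):
    same = po.place_residual(default_gt, (0, 0, 0))
    assert np.array_equal(same.v2_mask, default_gt.v2_mask)
    moved = po.place_residual(default_gt, (2, -1, 3))
    assert moved.v2_mask.sum() == default_gt.v2_mask.sum()
    assert moved.offset == (2, -1, 3)
    with pytest.raises(ValueError):
        po.place_residual(default_gt, (40, 0, 0))  # violates border margin


def test_metrics_invariant_under_common_shift(default_gt):
    gt = po.place_residual(default_gt, (2, -2, -2))
    ref = po.overlap_metrics(gt.v1_mask, gt.v2_mask)
    shifted = po.overlap_metrics(np.roll(gt.v1_mask, (1, 2, 0), (0, 1, 2)),
                                 np.roll(gt.v2_mask, (1, 2, 0), (0, 1, 2)))
    assert shifted.dice == pytest.approx(ref.dice)
    assert shifted.of == pytest.approx(ref.of)


def _cuboid_gt(length=13):
    """A hand-checkable ground truth with a 13-voxel-long 1x1 cuboid V1 = V2."""
    grid = po.VoxelGrid((24, 24, 24))
    tumour = np.zeros(grid.shape, bool)
    tumour[5:18, 8:10, 8:10] = True  # 52 voxels: v1 holds 25% of the tumour
    v1 = np.zeros(grid.shape, bool)
    v1[5:18, 9, 9] = True  # 13 voxels
    gt = po.GroundTruth(grid=grid, tumour_mask=tumour, v1_mask=v1,
                        v2_mask=v1.copy())
    return gt


def test_one_voxel_shift_of_cuboid():
    """Dice of a 13-voxel segment against itself shifted by one voxel is 12/13
    (12 of 13 voxels still coincide)."""
    gt = _cuboid_gt()
    moved = po.place_residual(gt, (1, 0, 0))
    rep = po.overlap_metrics(gt.v1_mask, moved.v2_mask)
    assert rep.dice == pytest.approx(12 / 13)
    assert rep.of == pytest.approx(12 / 13)


# ----------------------------------------------------------------- solve_offset

def _brute_force_best(gt, target, metric, radius):
    best = None
    n1, n2 = gt.v1_mask.sum(), gt.v2_mask.sum()
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                try:
                    moved = po.place_residual(gt, (dx, dy, dz))
                except ValueError:
                    continue
                inter = (gt.v1_mask & moved.v2_mask).sum()
                if metric == "dice":
                    val = 2 * inter / (n1 + n2)
                else:
                    val = (2 * inter / (n1 + n2) + inter / min(n1, n2)
                           + inter / n1 + inter / n2) / 4
                key = (abs(val - target), dx * dx + dy * dy + dz * dz, (dx, dy, dz))
                if best is None or key < best[0]:
                    best = (key, (dx, dy, dz), val)
    return best[1], best[2]


@pytest.mark.parametrize("target,metric", [(0.5, "mean4"), (0.5, "dice"),
                                           (0.2, "mean4"), (1.0, "mean4")])
def test_solve_offset_matches_brute_force(target, metric):
    """Exhaustive enumeration on a small instance agrees with the FFT search."""
    grid = po.VoxelGrid((16, 16, 16))
    v1 = np.zeros(grid.shape, bool)
    v1[5:10, 5:10, 6:10] = True
    tumour = ndimage.binary_dilation(v1, iterations=2)
    tumour &= np.pad(np.ones((10, 10, 10), bool), 3)
    gt = po.GroundTruth(grid=grid, tumour_mask=tumour, v1_mask=v1,
                        v2_mask=v1.copy())
    got_off, got_val = po.solve_offset(gt, target, metric=metric, radius=4)
    exp_off, exp_val = _brute_force_best(gt, target, metric, radius=4)
    assert got_off == exp_off
    assert got_val == pytest.approx(exp_val)


def test_solve_offset_perfect_target_is_identity(default_gt):
    gt = dataclasses.replace(default_gt, v2_mask=default_gt.v1_mask.copy())
    off, val = po.solve_offset(gt, 1.0, radius=3)
    assert off == (0, 0, 0)
    assert val == 1.0


def test_canonical_configurations(canonical_gts):
    """The packaged offsets realise overlaps of ~0.77, ~0.35 and exactly 0."""
    means = {}
    for name, gt in canonical_gts.items():
        rep = po.overlap_metrics(gt.v1_mask, gt.v2_mask)
        means[name] = rep.mean4
    assert round(means["high"], 2) == 0.77
    assert round(means["low"], 2) == 0.35
    rep0 = po.overlap_metrics(canonical_gts["none"].v1_mask,
                              canonical_gts["none"].v2_mask)
    assert rep0.dice == rep0.of == rep0.x == rep0.y == 0.0


# ---------------------------------------------------------------- rendering

def test_degenerate_formation_is_exact(canonical_gts, default_config):
    """No blur, no noise: the image is the piecewise-constant activity map."""
    gt = canonical_gts["high"]
    cfg = dataclasses.replace(default_config, psf_fwhm=0.0, noise_cv=0.0)
    pet2 = po.render(gt, cfg, "PET2")
    act = pet2.meta["activities"]["v2"]
    expected = np.where(gt.v2_mask, act, 1.0)
    assert np.abs(pet2.values - expected).max() == 0.0
    bg = po.background_region(gt, "PET2")
    assert po.measured_contrast(pet2, gt.v2_mask, bg) == pytest.approx(2.0)
    pet1 = po.render(gt, cfg, "PET1")
    assert po.measured_contrast(pet1, gt.v1_mask,
                                po.background_region(gt, "PET1")) == pytest.approx(6.0)


def test_rendered_contrasts(pet_pair, canonical_gts):
    pet1, pet2 = pet_pair
    gt = canonical_gts["high"]
    bg1 = po.background_region(gt, "PET1")
    assert po.measured_contrast(pet1, gt.tumour_mask, bg1) == pytest.approx(3.0, rel=0.05)
    assert po.measured_contrast(pet1, gt.v1_mask, bg1) == pytest.approx(6.0, rel=0.05)
    bg2 = po.background_region(gt, "PET2")
    assert po.measured_contrast(pet2, gt.v2_mask, bg2) == pytest.approx(2.0, rel=0.05)


def test_measured_contrast_edges(pet_pair, canonical_gts):
    pet1, _ = pet_pair
    gt = canonical_gts["high"]
    assert po.measured_contrast(pet1, gt.v1_mask, gt.v1_mask) == 1.0
    with pytest.raises(ValueError):
        po.measured_contrast(pet1, np.zeros(gt.grid.shape, bool), gt.v1_mask)


def test_partial_volume_effect_monotone(canonical_gts, default_config):
    """Measured contrast of the small V1 region never rises with more blur."""
    gt = canonical_gts["high"]
    contrasts = []
    for fwhm in (0.0, 5.0, 10.0):
        cfg = dataclasses.replace(default_config, psf_fwhm=fwhm, noise_cv=0.0,
                                  contrast_v1_tumourrest=2.0)
        act = {"v1": 6.0, "tumour_rest": 2.25}  # fixed activities: pure PSF effect
        from petoverlap.phantom import _activity_map, _blur
        img = po.SimulatedImage(gt.grid, _blur(_activity_map(gt, cfg, "PET1", act), cfg))
        contrasts.append(po.measured_contrast(img, gt.v1_mask,
                                              po.background_region(gt, "PET1")))
    assert contrasts[0] >= contrasts[1] >= contrasts[2]
    assert contrasts[2] < 6.0


def test_render_reproducible_and_seed_sensitivity(canonical_gts, default_config):
    gt = canonical_gts["high"]
    a = po.render(gt, default_config, "PET1")
    b = po.render(gt, default_config, "PET1")
    assert np.array_equal(a.values, b.values)
    other = po.render(gt, default_config, "PET1", noise_seed=12345)
    assert not np.array_equal(a.values, other.values)
    # noise is multiplicative and zero-mean: regional means are stable
    mean_a = a.values[gt.tumour_mask].mean()
    mean_o = other.values[gt.tumour_mask].mean()
    assert abs(mean_a - mean_o) / mean_a < 0.02
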