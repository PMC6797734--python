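"""Shared fixtures: the default phantom, its canonical configurations and the
rendered PET pair. Session-scoped because the phantom build and the Bayesian
fits are reused by many tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import petoverlap as po


@pytest.fixture(scope="session")
def default_config() -> po.PhantomConfig:
    return po.PhantomConfig()


@pytest.fixture(scope="session")
def default_gt(default_config) -> po.GroundTruth:
    return po.build_ground_truth(default_config)


@pytest.fixture(scope="session")
def canonical_gts(default_gt) -> dict[str, po.GroundTruth]:
    return {name: po.place_residual(default_gt, po.canonical_offset(name))
            for name in ("high", "low", "none")}


@pytest.fixture(scope="session")
def pet_pair(canonical_gts, default_config):
    """Rendered PET1/PET2 of the high-overlap configuration (default seed)."""
    gt = canonical_gts["high"]
    return (po.render(gt, default_config, "PET1"),
            po.render(gt, default_config, "PET2"))


@pytest.fixture(scope="session")
def rois(canonical_gts):
    gt = canonical_gts["high"]
    return (po.roi_from_mask(gt.tumour_mask, margin=3),
            po.roi_from_mask(gt.v2_mask, margin=3))


@pytest.fixture(scope="session")
def flab_results(pet_pair, rois):
    pet1, pet2 = pet_pair
    roi1, roi2 = rois
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return (po.flab_segment(pet1, roi1, n_classes=3),
                po.flab_segment(pet2, roi2, n_classes=2))


@pytest.fixture(scope="session")
def mixed_cohort():
    """A 10-case mixed-site synthetic cohort (registration included)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return po.synth_cohort(10, "mixed", seed=11)


def random_mask_pair(rng: np.random.Generator, shape=(16, 16, 16)):
    """Two random non-empty overlapping-or-not boolean masks."""
    a = rng.random(shape) < rng.uniform(0.05, 0.5)
    b = rng.random(shape) < rng.uniform(0.05, 0.5)
    if not a.any():
        a[tuple(rng.integers(0, s) for s in shape)] = True
    if not b.any():
        b[tuple(rng.integers(0, s) for s in shape)] = True
    return a, b
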