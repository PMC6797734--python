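"""Recover a known rigid misalignment of a noisy PET image.

The moving image is the fixed image shifted by two voxels (8 mm) with 5%
multiplicative noise. Mutual-information registration from a centre-of-mass
initialisation should recover the shift to well under one voxel.
"""

import numpy as np

import petoverlap as po

gt, config = po.canonical_phantom("high")
fixed = po.render(gt, config, "PET1")

rng = np.random.default_rng(1)
moved = np.roll(fixed.values, 2, axis=0)
noisy = np.clip(moved * (1 + 0.05 * rng.standard_normal(moved.shape)), 0, None)
moving = po.SimulatedImage(fixed.grid, noisy)

transform = po.register_rigid(fixed, moving)
print(f"applied shift   : [8. 0. 0.] mm")
print(f"recovered shift : {np.round(transform.translation, 3)} mm")
err = np.abs(np.asarray(transform.translation) - [8.0, 0.0, 0.0]).max()
print(f"max axis error  : {err:.3f} mm ({err / 4:.2f} voxels)")

realigned = po.apply_transform(moving, transform, interpolation="sinc")
print(f"mean |realigned - fixed| over the tumour: "
      f"{np.abs(realigned.values - fixed.values)[gt.tumour_mask].mean():.3f} "
      f"(noise floor ~0.2)")
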