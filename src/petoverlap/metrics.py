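"""Overlap metrics between binary masks, and ground-truth overlap accuracy.

The four metrics follow the conventions of the pre-/post-treatment sub-volume
overlap literature, computed on voxel counts (all ratios are spacing
invariant)::

    Dice = 2|V1 n V2| / (|V1| + |V2|)
    OF   = |V1 n V2| / min(|V1|, |V2|)      (overlap fraction)
    X    = |V1 n V2| / |V1|
    Y    = |V1 n V2| / |V2|

Jaccard is computed as well but is redundant with Dice for ranking
(J = D / (2 - D)). Overlap accuracy compares the *estimated* overlap region
O_est = V1_est n V2_est with the ground-truth overlap O_gt = V1_gt n V2_gt as
the mean of positive predictive value and sensitivity; it is undefined (None)
when O_gt is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OverlapReport", "overlap_metrics", "overlap_accuracy"]


@dataclass(frozen=True)
class OverlapReport:
    dice: float
    of: float
    x: float
    y: float
    jaccard: float
    vol_v1: float  # cm^3
    vol_v2: float  # cm^3
    vol_intersection: float  # cm^3
    accuracy: float | None = None

    @property
    def mean4(self) -> float:
        """Mean of Dice, OF, X and Y."""
        return (self.dice + self.of + self.x + self.y) / 4.0

    def as_dict(self) -> dict:
        return {
            "dice": self.dice, "of": self.of, "x": self.x, "y": self.y,
            "jaccard": self.jaccard, "vol_v1_cm3": self.vol_v1,
            "vol_v2_cm3": self.vol_v2, "vol_intersection_cm3": self.vol_intersection,
            "accuracy": self.accuracy,
        }


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")


def overlap_metrics(v1: np.ndarray, v2: np.ndarray,
                    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
                    accuracy: float | None = None) -> OverlapReport:
    """Compute Dice, OF, X, Y, Jaccard and volumes for two non-empty masks."""
    _check_pair(v1, v2)
    n1 = int(np.count_nonzero(v1))
    n2 = int(np.count_nonzero(v2))
    if n1 == 0 or n2 == 0:
        raise ValueError("overlap metrics require non-empty masks")
    ni = int(np.count_nonzero(v1 & v2))
    nu = n1 + n2 - ni
    vox_cm3 = float(np.prod(spacing)) / 1000.0
    return OverlapReport(
        dice=2.0 * ni / (n1 + n2),
        of=ni / min(n1, n2),
        x=ni / n1,
        y=ni / n2,
        jaccard=ni / nu,
        vol_v1=n1 * vox_cm3,
        vol_v2=n2 * vox_cm3,
        vol_intersection=ni * vox_cm3,
        accuracy=accuracy,
    )


def overlap_accuracy(v1_est: np.ndarray, v2_est: np.ndarray,
                     v1_gt: np.ndarray, v2_gt: np.ndarray) -> float | None:
    """Mean of PPV and sensitivity of the estimated overlap region.

    Returns None when the ground-truth overlap is empty (accuracy undefined,
    reported as "N/A"). PPV is taken as 0 when the estimated overlap is empty
    while the ground-truth overlap is not.
    """
    _check_pair(v1_est, v2_est)
    _check_pair(v1_est, v1_gt)
    _check_pair(v1_gt, v2_gt)
    o_est = v1_est & v2_est
    o_gt = v1_gt & v2_gt
    n_gt = int(np.count_nonzero(o_gt))
    if n_gt == 0:
        return None
    n_est = int(np.count_nonzero(o_est))
    n_tp = int(np.count_nonzero(o_est & o_gt))
    ppv = n_tp / n_est if n_est > 0 else 0.0
    se = n_tp / n_gt
    return (ppv + se) / 2.0
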