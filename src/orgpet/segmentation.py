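"""Isocontour delineation of the metabolic tumor volume (MTV).

The VOI is the set of voxels at or above a fixed fraction (default 40%) of
the maximum SUV inside an annotated seed region, restricted to the
26-connected component that contains the maximum voxel.  Voxels belonging to
adjacent physiological uptake (duodenum, biliary stent) can be excluded via a
mask; the reference maximum is computed *after* exclusion so spill-over
never sets the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .phantom import PhantomImage

__all__ = ["VOIMask", "isocontour_voi", "mtv", "seed_mask_from_truth"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VOIMask:
    """Boolean VOI with the threshold provenance that produced it."""

    mask: np.ndarray
    threshold_suv: float
    suvmax_ref: float
    n_voxels: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if int(mask.sum()) != self.n_voxels:
            raise ValueError("n_voxels inconsistent with mask")


def isocontour_voi(
    image: PhantomImage,
    seed_mask: np.ndarray,
    fraction: float = 0.40,
    exclusion_mask: Optional[np.ndarray] = None,
) -> VOIMask:
    """Fractional-SUVmax isocontour VOI within the seed region.

    threshold = fraction * max(image over seed minus exclusions); the
    returned mask is the 26-connected component of above-threshold voxels
    containing the maximum voxel.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    seed = np.asarray(seed_mask, dtype=bool)
    if seed.shape != image.shape:
        raise ValueError("seed mask shape does not match image")
    region = seed.copy()
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != image.shape:
            raise ValueError("exclusion mask shape does not match image")
        region &= ~excl
    if not region.any():
        raise ValueError("seed region is empty after exclusion subtraction")

    vals = image.values
    suvmax = float(vals[region].max())
    threshold = fraction * suvmax
    candidates = region & (vals >= threshold)

    labels, _ = ndimage.label(candidates, structure=_STRUCT_26)
    # the max voxel always qualifies; pick its component
    flat_region = np.where(region, vals, -np.inf)
    max_idx = np.unravel_index(int(np.argmax(flat_region)), vals.shape)
    mask = labels == labels[max_idx]
    return VOIMask(
        mask=mask,
        threshold_suv=threshold,
        suvmax_ref=suvmax,
        n_voxels=int(mask.sum()),
        provenance={
            "fraction": float(fraction),
            "n_seed": int(seed.sum()),
            "n_excluded": 0 if exclusion_mask is None else int(np.asarray(exclusion_mask, bool).sum()),
        },
    )


def mtv(voi: VOIMask, spacing_mm: Sequence[float]) -> float:
    """Metabolic tumor volume in milliliters (voxel count x voxel volume)."""
    voxel_mm3 = float(np.prod([float(s) for s in spacing_mm]))
    return voi.n_voxels * voxel_mm3 / 1000.0


def seed_mask_from_truth(
    truth: PhantomImage,
    background_suv: float,
    dilate_voxels: int = 2,
    motion_axis: Optional[int] = None,
    max_shift_mm: float = 0.0,
    support_fraction: float = 0.05,
) -> np.ndarray:
    """Deterministic stand-in for the manual tumor annotation.

    Bounding box of the lesion foreground (> support_fraction of the peak
    excess over background), optionally extended along the motion axis by the
    maximal displacement (the annotator outlines the motion-smeared lesion),
    then dilated by ``dilate_voxels``.
    """
    excess = truth.values - background_suv
    peak = excess.max()
    if peak <= 0:
        raise ValueError("truth has no lesion foreground above background")
    support = excess > support_fraction * peak
    lo = [int(np.nonzero(support.any(axis=tuple(a for a in range(3) if a != ax)))[0][0]) for ax in range(3)]
    hi = [int(np.nonzero(support.any(axis=tuple(a for a in range(3) if a != ax)))[0][-1]) for ax in range(3)]
    if motion_axis is not None and max_shift_mm != 0.0:
        shift_vox = int(np.ceil(abs(max_shift_mm) / truth.spacing_mm[motion_axis]))
        if max_shift_mm > 0:
            hi[motion_axis] += shift_vox
        else:
            lo[motion_axis] -= shift_vox
    mask = np.zeros(truth.shape, dtype=bool)
    sl = tuple(
        slice(max(0, lo[ax] - dilate_voxels), min(truth.shape[ax], hi[ax] + dilate_voxels + 1))
        for ax in range(3)
    )
    mask[sl] = True
    return mask
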