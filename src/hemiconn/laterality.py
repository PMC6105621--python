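"""Interhemispheric laterality of seed connectivity.

LI = (n_AD - n_NAND) / (n_AD + n_NAND), where n_AD counts suprathreshold
voxels inside the affected/dominant homotopic ROI (intra-hemispheric
connectivity, the seed's own side) and n_NAND those inside the
non-affected/non-dominant ROI.  LI = +1 means purely intra-hemispheric
connectivity, -1 purely interhemispheric, 0 symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LateralityResult", "laterality_index", "split_mask_by_midline"]


@dataclass
class LateralityResult:
    li: float
    count_AD: int
    count_NAND: int
    seed_id: str = ""
    input_map: str = "surviving"  # which thresholded map fed the counts

    def __post_init__(self):
        if not -1.0 <= self.li <= 1.0:
            raise ValueError("LI outside [-1, 1]")


def split_mask_by_midline(mask, lr_axis=None):
    """Split a bilateral mask into two hemisphere masks at the mid-sagittal
    plane.  Voxels on the grid's own half-spaces are assigned by index;
    the midline voxel column (odd-length axis) is excluded from both."""
    from dataclasses import replace

    ax = mask.lr_axis if lr_axis is None else lr_axis
    n = mask.data.shape[ax]
    idx = np.arange(n)
    lo = idx < n // 2
    hi = idx >= (n + 1) // 2
    shape = [1, 1, 1]
    shape[ax] = n
    lo = lo.reshape(shape)
    hi = hi.reshape(shape)
    left = replace(mask)
    left.data = mask.data * lo
    right = replace(mask)
    right.data = mask.data * hi
    return left, right


def laterality_index(surviving, roi_AD, roi_NAND, seed_id="", input_map="surviving"):
    """Laterality index of a suprathreshold connectivity mask.

    The two ROIs must be disjoint (enforce with
    :func:`split_mask_by_midline` if a bilateral atlas mask crosses the
    midline) and at least one of the two counts must be nonzero.
    """
    for roi in (roi_AD, roi_NAND):
        if not surviving.same_grid(roi):
            raise ValueError("grid mismatch between map and ROI")
    if np.any((roi_AD.data > 0) & (roi_NAND.data > 0)):
        raise ValueError("ROIs overlap; split them at the midline first")
    n_ad = int(((surviving.data > 0) & (roi_AD.data > 0)).sum())
    n_nand = int(((surviving.data > 0) & (roi_NAND.data > 0)).sum())
    if n_ad + n_nand == 0:
        raise ValueError("no suprathreshold connectivity in either ROI")
    li = (n_ad - n_nand) / (n_ad + n_nand)
    return LateralityResult(li=li, count_AD=n_ad, count_NAND=n_nand,
                            seed_id=seed_id, input_map=input_map)
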