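"""Lesion-derived anatomical markers.

The weighted corticospinal-tract lesion load (wCST-LL) scores the overlap
between a lesion mask and a probabilistic tract map: every intersecting
voxel contributes one tenth of its tract probability (percent scale) times
the voxel volume, giving a probability-weighted overlap volume in mm^3.
A lesion entirely inside a region of uniform probability p (percent)
therefore scores n_voxels * (p / 10) * voxel_volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import BinaryMask, BoldRun, ProbMap

__all__ = ["WcstResult", "wcst_ll", "apply_lesion_exclusion"]


@dataclass
class WcstResult:
    wcst_ll: float          # weighted lesion load, mm^3
    n_max: int              # intersecting voxels between lesion and tract
    voxel_volume: float     # mm^3
    overlap_mm3: float      # unweighted overlap volume, n_max * voxel_volume
    probability_scale: str  # scale the tract map was declared on
    weighting: str          # 'linear' or 'squared'

    def as_dict(self):
        return {
            "wcst_ll": self.wcst_ll,
            "n_max": self.n_max,
            "voxel_volume": self.voxel_volume,
            "overlap_mm3": self.overlap_mm3,
            "probability_scale": self.probability_scale,
            "weighting": self.weighting,
        }


def wcst_ll(lesion, tract, tract_threshold=0.0, weighting="linear"):
    """Weighted CST lesion load of a lesion against a probabilistic tract.

    Sums (1/10) * I(n) * voxel_volume over the voxels n where the lesion
    is 1 and the tract probability exceeds ``tract_threshold`` (a
    fraction); I(n) is the tract probability expressed on the percent
    scale.  With ``weighting="squared"`` the per-voxel weight uses
    I(n)^2 / 100 instead, an alternative reading of the published
    formula in which the probability enters twice.

    Returns a :class:`WcstResult`; ``wcst_ll`` is 0 exactly when the
    intersection is empty.
    """
    if not lesion.same_grid(tract):
        raise ValueError("grid mismatch: lesion and tract must share a grid")
    if weighting not in ("linear", "squared"):
        raise ValueError("weighting must be 'linear' or 'squared'")
    prob_pct = tract.as_fraction() * 100.0
    inter = (lesion.data > 0) & (prob_pct > tract_threshold * 100.0) & (prob_pct > 0)
    n_max = int(inter.sum())
    vv = lesion.voxel_volume
    w = prob_pct[inter]
    if weighting == "squared":
        w = w * w / 100.0
    value = float(0.1 * w.sum() * vv)
    return WcstResult(
        wcst_ll=value,
        n_max=n_max,
        voxel_volume=vv,
        overlap_mm3=n_max * vv,
        probability_scale=tract.scale,
        weighting=weighting,
    )


def apply_lesion_exclusion(obj, lesion):
    """Zero out lesioned voxels so they drop from all downstream statistics.

    Works on runs (every volume), probability/statistic volumes and
    binary masks; the returned object is of the same type as the input.
    """
    if isinstance(obj, BoldRun):
        if not obj.same_grid(lesion):
            raise ValueError("grid mismatch: lesion not on the run's grid")
        out = BoldRun(data=obj.data.copy(), tr=obj.tr, affine=obj.affine)
        out.data[lesion.data > 0, :] = 0.0
        return out
    if not obj.same_grid(lesion):
        raise ValueError("grid mismatch: lesion not on the image's grid")
    out = replace(obj)
    out.data = obj.data.copy()
    out.data[lesion.data > 0] = 0.0
    return out
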