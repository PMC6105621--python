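"""Image containers, NIfTI I/O and signal-level primitives.

Everything downstream (lesion scoring, seed connectivity, laterality,
the phantom generator) operates on the small set of containers defined
here: 3-D volumes, 4-D BOLD runs, binary masks and probabilistic maps,
all carried on an explicit voxel grid with an affine and millimetre
voxel dimensions.  Masks and maps never resample implicitly: a grid
mismatch is an error, not a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "BoldRun",
    "BinaryMask",
    "ProbMap",
    "read_volume",
    "write_volume",
    "read_motion",
    "write_motion",
    "mirror_lr",
    "threshold_binarize",
    "mask_stats",
    "discard_initial",
    "gaussian_smooth",
    "highpass_gaussian_line",
    "grand_mean_normalize",
    "extract_tissue_ts",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _default_affine(voxel_dims):
    aff = np.diag(list(voxel_dims) + [1.0])
    return aff


def _axis_codes(affine):
    """Axis orientation codes ('R'/'L', 'A'/'P', 'S'/'I') per array axis."""
    return nib.orientations.aff2axcodes(affine)


def _lr_axis(affine):
    """Index of the array axis aligned with the subject's left-right axis."""
    for i, code in enumerate(_axis_codes(affine)):
        if code in ("L", "R"):
            return i
    raise ValueError("orientation tag does not identify a left-right axis")


@dataclass
class VolumeImage:
    """A 3-D scalar volume on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z)
        Finite voxel values.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world transform; defaults to a scaled identity built
        from ``voxel_dims``.
    voxel_dims : tuple of float
        Voxel edge lengths in mm, all positive.
    """

    data: np.ndarray
    affine: np.ndarray = None
    voxel_dims: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("unsupported dimensionality: expected a 3-D volume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_dims)
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_dims = tuple(
            float(v) for v in nib.affines.voxel_sizes(self.affine)
        )
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        if self.data.shape[_lr_axis(self.affine)] < 2:
            raise ValueError("grid must extend at least 2 voxels left-right")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self):
        """Voxel volume in mm^3 (product of the voxel dimensions)."""
        return float(np.prod(self.voxel_dims))

    @property
    def orientation_tag(self):
        return "".join(_axis_codes(self.affine))

    @property
    def lr_axis(self):
        return _lr_axis(self.affine)

    def same_grid(self, other):
        return self.shape == other.shape[:3] and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def _require_same_grid(self, other, what="operand"):
        if not self.same_grid(other):
            raise ValueError(f"grid mismatch: {what} is not on this image's grid")


@dataclass
class BoldRun:
    """A 4-D BOLD run (x, y, z, t) with repetition time ``tr`` seconds."""

    data: np.ndarray
    tr: float
    affine: np.ndarray = None
    voxel_dims: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("unsupported dimensionality: expected a 4-D run")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD run contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_dims)
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_dims = tuple(
            float(v) for v in nib.affines.voxel_sizes(self.affine)
        )
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_volumes(self):
        return self.data.shape[3]

    @property
    def voxel_volume(self):
        return float(np.prod(self.voxel_dims))

    @property
    def lr_axis(self):
        return _lr_axis(self.affine)

    def same_grid(self, other):
        return self.shape[:3] == other.shape[:3] and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class BinaryMask(VolumeImage):
    """A {0,1} volume sharing the grid of a reference image."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(float)

    @property
    def voxel_count(self):
        return int(self.data.sum())


@dataclass
class ProbMap(VolumeImage):
    """A probability volume with an explicitly declared scale.

    ``scale`` is ``"fraction"`` (values in [0, 1]) or ``"percent"``
    (values in [0, 100]); the declaration is part of the contract and
    checked on construction.
    """

    scale: str = "fraction"

    def __post_init__(self):
        super().__post_init__()
        if self.scale not in ("fraction", "percent"):
            raise ValueError("scale must be 'fraction' or 'percent'")
        hi = 1.0 if self.scale == "fraction" else 100.0
        if self.data.min() < 0 or self.data.max() > hi + 1e-9:
            raise ValueError(f"values outside declared {self.scale} range")

    def as_fraction(self):
        """Values on the [0, 1] scale regardless of the declared scale."""
        return self.data / 100.0 if self.scale == "percent" else self.data


# ---------------------------------------------------------------------------
# I/O


def read_volume(path, tr=None):
    """Read a NIfTI-1 file into a :class:`VolumeImage` or :class:`BoldRun`.

    4-D payloads become :class:`BoldRun`; the TR is taken from the header
    pixdim unless overridden by ``tr``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 3:
        return VolumeImage(data=data, affine=img.affine)
    if data.ndim == 4:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        tr = float(tr) if tr is not None else header_tr
        if tr <= 0:
            raise ValueError("TR not recorded in header; pass tr explicitly")
        return BoldRun(data=data, tr=tr, affine=img.affine)
    raise ValueError(f"unsupported dimensionality: {data.ndim}-D payload")


def write_volume(obj, path):
    """Write a container to NIfTI-1, preserving affine and (for runs) TR."""
    img = nib.Nifti1Image(np.asarray(obj.data, dtype=np.float64), obj.affine)
    if isinstance(obj, BoldRun):
        zooms = list(img.header.get_zooms())
        zooms[3] = obj.tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    img.to_filename(str(path))


def read_motion(path, n_volumes=None):
    """Read a whitespace-delimited 6-column motion-parameter table."""
    table = np.loadtxt(str(path), ndmin=2)
    if table.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns")
    if not np.all(np.isfinite(table)):
        raise ValueError("motion table contains non-finite values")
    if n_volumes is not None and table.shape[0] != n_volumes:
        raise ValueError(
            f"motion table rows ({table.shape[0]}) != run volumes ({n_volumes})"
        )
    return table


def write_motion(table, path):
    np.savetxt(str(path), np.asarray(table, dtype=float), fmt="%.8f")


# ---------------------------------------------------------------------------
# Geometric / signal primitives


def mirror_lr(v):
    """Reflect a volume or run across the mid-sagittal plane.

    The left-right array axis is identified from the affine's orientation
    codes; every other piece of metadata is unchanged, so the operation
    is an involution.
    """
    ax = _lr_axis(v.affine)
    out = replace(v)
    out.data = np.flip(v.data, axis=ax).copy()
    return out


def threshold_binarize(p, thr):
    """Binarize a probability map at a fractional threshold (inclusive >=).

    ``thr`` is always on the fraction scale; percent-scale maps are
    converted before comparison.
    """
    if not (0.0 < thr < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    mask = (p.as_fraction() >= thr - 1e-12).astype(float)
    return BinaryMask(data=mask, affine=p.affine)


def mask_stats(m):
    """Voxel count and volume (mm^3) of a binary mask."""
    n = int(m.data.sum())
    return {"voxel_count": n, "volume_mm3": n * m.voxel_volume}


def discard_initial(b, k=5):
    """Drop the first ``k`` volumes of a run (steady-state discard)."""
    if not 0 <= k < b.n_volumes:
        raise ValueError("k must satisfy 0 <= k < number of volumes")
    return BoldRun(data=b.data[..., k:].copy(), tr=b.tr, affine=b.affine)


def gaussian_smooth(obj, fwhm_mm):
    """Spatial Gaussian smoothing with a kernel of the given FWHM in mm.

    Anisotropic voxels are handled by a per-axis sigma of
    ``fwhm / (2 sqrt(2 ln 2)) / voxel_dim``; boundaries use symmetric
    reflection, which preserves constants and the in-volume sum.
    """
    from scipy.ndimage import gaussian_filter

    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        out = replace(obj)
        out.data = obj.data.copy()
        return out
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / d for d in obj.voxel_dims]
    out = replace(obj)
    if obj.data.ndim == 3:
        out.data = gaussian_filter(obj.data, sigmas, mode="reflect")
    else:
        out.data = gaussian_filter(obj.data, sigmas + [0.0], mode="reflect")
    return out


def _running_line_hat(t, sigma_vols):
    """Hat matrix of a Gaussian-weighted local linear fit, one row per point."""
    idx = np.arange(t, dtype=float)
    H = np.empty((t, t))
    for i in range(t):
        w = np.exp(-0.5 * ((idx - i) / sigma_vols) ** 2)
        sw = w.sum()
        x = idx - (w @ idx) / sw
        sxx = w @ (x * x)
        # fitted value at point i of the weighted straight line
        H[i] = w / sw + x[i] * (w * x) / sxx
    return H


def highpass_gaussian_line(b, sigma_s=100.0):
    """Temporal high-pass by Gaussian-weighted running-line detrending.

    At every time point a straight line is fitted to the whole series by
    weighted least squares with Gaussian weights ``exp(-dt^2 / 2 sigma^2)``
    centred on that point, and the fitted value is subtracted.  The
    residual series is then re-centred on the original temporal mean, so
    the mean is preserved exactly and affine-in-time inputs are reduced
    to their mean.
    """
    if sigma_s <= 0:
        raise ValueError("sigma must be positive")
    t = b.n_volumes
    if t < 3:
        raise ValueError("need at least 3 time points")
    H = _running_line_hat(t, sigma_s / b.tr)
    flat = b.data.reshape(-1, t)
    resid = flat - flat @ H.T
    out = resid - resid.mean(axis=1, keepdims=True) + flat.mean(axis=1, keepdims=True)
    return BoldRun(data=out.reshape(b.data.shape), tr=b.tr, affine=b.affine)


def grand_mean_normalize(b, brain=None, target=10000.0):
    """Scale a run so its 4-D in-mask mean equals ``target`` (default 10000)."""
    if brain is not None:
        sel = b.data[brain.data > 0]
    else:
        sel = b.data
    mean = float(sel.mean())
    if abs(mean) < 1e-12:
        raise ValueError("zero mean: cannot grand-mean normalize")
    return BoldRun(data=b.data * (target / mean), tr=b.tr, affine=b.affine)


def extract_tissue_ts(b, csf, wm, gm, threshold=0.80):
    """Mean CSF, WM and GM time series at >= ``threshold`` tissue probability.

    Returns three 1-D arrays of length ``b.n_volumes``.
    """
    out = []
    for name, pmap in (("CSF", csf), ("WM", wm), ("GM", gm)):
        if pmap.data.shape != b.shape[:3] or not np.allclose(
            pmap.affine, b.affine, atol=1e-6
        ):
            raise ValueError(f"{name} map is not on the run's grid")
        sel = pmap.as_fraction() >= threshold - 1e-12
        if not sel.any():
            raise ValueError(f"empty tissue mask: no {name} voxel reaches {threshold:.0%}")
        out.append(b.data[sel].mean(axis=0))
    return tuple(out)
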