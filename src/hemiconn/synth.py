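"""Synthetic phantoms: anatomy, lesions, BOLD runs and cohorts.

The generator exists so the whole pipeline is testable without any
imaging download.  It emulates:

* a two-hemisphere ellipsoidal "brain" with CSF shell, WM core and GM
  ribbon compartments on a 32 x 32 x 24 grid of 3 mm voxels;
* bilateral S1- and M1-like probabilistic ROIs (Gaussian bumps peaking
  at 1, exact left/right mirror images) plus occipital and parietal
  satellites;
* a CST-like probabilistic tract descending through one hemisphere;
* ellipsoidal lesions whose overlap with the tract can be driven to a
  target fraction by bisection on the radius;
* BOLD runs built from a shared-latent-factor model, so every planted
  ROI-pair correlation has a closed form usable as a test oracle;
* cohorts with known linear marker-to-score coefficients.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BinaryMask, BoldRun, ProbMap, mirror_lr, threshold_binarize

__all__ = [
    "PhantomSpec",
    "CouplingSpec",
    "CohortSpec",
    "PhantomAnatomy",
    "make_phantom_anatomy",
    "make_lesion",
    "simulate_bold",
    "simulate_cohort",
    "planted_pair_correlation",
]


@dataclass
class PhantomSpec:
    shape: tuple = (32, 32, 24)
    voxel_dims: tuple = (3.0, 3.0, 3.0)
    lr_axis: int = 0
    # left-hemisphere ROI centres in voxel coordinates; right = mirror
    roi_centers: dict = field(default_factory=lambda: {
        "s1": (8.0, 19.0, 17.0),
        "m1": (8.0, 13.0, 17.0),
        "occipital": (8.0, 26.0, 11.0),
        "parietal": (8.0, 23.0, 15.0),
    })
    roi_sigma_vox: float = 1.8
    brain_semiaxes_vox: tuple = (14.0, 14.0, 10.0)
    wm_radius: float = 0.55      # fraction of brain radius
    gm_outer_radius: float = 0.85
    tract_sigma_vox: float = 1.5
    tract_hemisphere: str = "left"
    seed: int = 0

    def __post_init__(self):
        half = self.shape[self.lr_axis] / 2.0
        for name, c in self.roi_centers.items():
            margin = self.roi_sigma_vox
            if not (c[self.lr_axis] + margin < half):
                raise ValueError(f"ROI {name} not strictly within its hemisphere")
            if any(ci < 0 or ci >= s for ci, s in zip(c, self.shape)):
                raise ValueError(f"ROI {name} outside grid")


@dataclass
class PhantomAnatomy:
    tissue: dict       # name -> ProbMap (csf, wm, gm)
    rois: dict         # 's1_left', 's1_right', 'm1_left', 'm1_right', satellites
    tract: ProbMap
    brain: BinaryMask
    spec: PhantomSpec

    def roi_mask(self, name, threshold=0.10):
        return threshold_binarize(self.rois[name], threshold)


@dataclass
class CouplingSpec:
    """Planted connectivity of the latent-factor BOLD model.

    ``inter_coupling`` maps a homotopic pair name ('s1', 'm1') to the
    planted correlation of its left/right ROI latents, in [0, 1].
    ``intra_coupling`` is the weight tying same-hemisphere ROI latents
    through a shared hemisphere factor; the implied cross-correlation of
    two same-side ROIs is sqrt(1-c_a) sqrt(1-c_b) * intra_coupling.
    """

    inter_coupling: dict = field(default_factory=lambda: {"s1": 0.7, "m1": 0.7})
    intra_coupling: float = 0.3
    signal_amplitude: float = 2.0
    global_amplitude: float = 0.5
    noise_sd: float = 1.0
    csf_amplitude: float = 1.5
    wm_amplitude: float = 0.8
    drift_amplitude: float = 1.0
    drift_period_s: float = 300.0
    motion_leak: float = 0.2
    baseline: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        for k, c in self.inter_coupling.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"inter coupling for {k} outside [0, 1]")
        if not 0.0 <= self.intra_coupling <= 1.0:
            raise ValueError("intra coupling outside [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")


@dataclass
class CohortSpec:
    """Generating model for synthetic marker/outcome cohorts.

    Outcome = intercept + beta_lesion * lesion_volume + beta_li * li_s1
    + N(0, noise_sd), with Chedoke components clipped to [1, 7] and
    NIHSS to >= 0.  Lesion volumes are uniform on ``lesion_range`` (mm^3)
    and laterality indices uniform on ``li_range``.
    """

    n_patients: int = 8
    n_controls: int = 8
    coefficients: dict = field(default_factory=lambda: {
        "nihss":        {"intercept": 1.0, "beta_lesion": 1.0e-4, "beta_li": 4.0, "noise_sd": 1.0},
        "chedoke_arm":  {"intercept": 6.5, "beta_lesion": -8.0e-5, "beta_li": -3.0, "noise_sd": 0.7},
        "chedoke_hand": {"intercept": 6.5, "beta_lesion": -8.0e-5, "beta_li": -3.0, "noise_sd": 0.7},
        "chedoke_leg":  {"intercept": 6.0, "beta_lesion": -4.0e-5, "beta_li": 0.0, "noise_sd": 0.7},
        "chedoke_foot": {"intercept": 6.0, "beta_lesion": -6.0e-5, "beta_li": -1.0, "noise_sd": 0.7},
    })
    lesion_range: tuple = (500.0, 40000.0)
    li_range: tuple = (-0.2, 1.0)
    wcst_fraction: float = 0.3     # wcst_ll ~ fraction of lesion volume + noise
    missing: list = field(default_factory=list)  # (row_index, column) pairs
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients for any regression")

    def analytic_r2(self, outcome="nihss"):
        """Population R-squared of each block for independent uniform
        predictors: block 1 is lesion volume, block 2 adds LI."""
        c = self.coefficients[outcome]
        v_les = (self.lesion_range[1] - self.lesion_range[0]) ** 2 / 12.0
        v_li = (self.li_range[1] - self.li_range[0]) ** 2 / 12.0
        s_les = c["beta_lesion"] ** 2 * v_les
        s_li = c["beta_li"] ** 2 * v_li
        total = s_les + s_li + c["noise_sd"] ** 2
        return {"r2_block1": s_les / total,
                "r2_block2": (s_les + s_li) / total,
                "delta_r2": s_li / total}


# ---------------------------------------------------------------------------


def _grids(shape):
    return np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")


def make_phantom_anatomy(spec=None):
    """Deterministic phantom anatomy for a :class:`PhantomSpec`."""
    spec = spec or PhantomSpec()
    shape = spec.shape
    aff = np.diag(list(spec.voxel_dims) + [1.0])
    xs, ys, zs = _grids(shape)
    center = [(s - 1) / 2.0 for s in shape]
    rr = np.sqrt(
        ((xs - center[0]) / spec.brain_semiaxes_vox[0]) ** 2
        + ((ys - center[1]) / spec.brain_semiaxes_vox[1]) ** 2
        + ((zs - center[2]) / spec.brain_semiaxes_vox[2]) ** 2
    )
    brain = BinaryMask(data=(rr <= 1.0).astype(float), affine=aff)

    def radial_band(lo, hi, soft=0.03):
        # smooth indicator of lo <= rr < hi, 1 well inside the band
        up = 1.0 / (1.0 + np.exp((rr - hi) / soft))
        down = 1.0 / (1.0 + np.exp((lo - rr) / soft))
        return up * down * brain.data

    tissue = {
        "wm": ProbMap(data=np.clip(radial_band(-1.0, spec.wm_radius), 0, 1), affine=aff),
        "gm": ProbMap(data=np.clip(radial_band(spec.wm_radius, spec.gm_outer_radius), 0, 1), affine=aff),
        "csf": ProbMap(data=np.clip(radial_band(spec.gm_outer_radius, 1.0), 0, 1), affine=aff),
    }

    def bump(cvox):
        d2 = (xs - cvox[0]) ** 2 + (ys - cvox[1]) ** 2 + (zs - cvox[2]) ** 2
        return np.exp(-d2 / (2.0 * spec.roi_sigma_vox**2))

    rois = {}
    for name, c in spec.roi_centers.items():
        left = ProbMap(data=bump(c), affine=aff)
        rois[f"{name}_left"] = left
        rois[f"{name}_right"] = mirror_lr(left)

    # tract: Gaussian tube descending through one hemisphere's core
    cx, cy, _ = spec.roi_centers["m1"]
    if spec.tract_hemisphere == "right":
        cx = shape[spec.lr_axis] - 1 - cx
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    tract = np.exp(-d2 / (2.0 * spec.tract_sigma_vox**2))
    tract = tract * (zs <= spec.roi_centers["m1"][2]) * brain.data
    tract_map = ProbMap(data=tract, affine=aff)
    return PhantomAnatomy(tissue=tissue, rois=rois, tract=tract_map,
                          brain=brain, spec=spec)


def make_lesion(anatomy, center_vox, radius_mm, target_tract_overlap=None,
                tract_threshold=0.10, tol=0.05, max_radius_mm=120.0):
    """Ellipsoidal lesion mask; optionally sized to a target tract overlap.

    The overlap is the fraction of lesion voxels falling inside the
    thresholded tract; when a target is given, the radius is bisected
    until the achieved fraction is within ``tol`` of the target.
    """
    spec = anatomy.spec
    aff = anatomy.brain.affine
    if anatomy.brain.data[tuple(int(round(c)) for c in center_vox)] == 0:
        raise ValueError("lesion center outside the brain")
    xs, ys, zs = _grids(spec.shape)

    def sphere(radius_mm):
        if radius_mm <= 0:
            return np.zeros(spec.shape)
        d2 = (
            ((xs - center_vox[0]) * spec.voxel_dims[0]) ** 2
            + ((ys - center_vox[1]) * spec.voxel_dims[1]) ** 2
            + ((zs - center_vox[2]) * spec.voxel_dims[2]) ** 2
        )
        return (d2 <= radius_mm**2).astype(float) * anatomy.brain.data

    tract_mask = threshold_binarize(anatomy.tract, tract_threshold).data > 0

    def overlap(mask):
        n = mask.sum()
        if n == 0:
            return 0.0
        return float((mask.astype(bool) & tract_mask).sum() / n)

    if target_tract_overlap is None:
        return BinaryMask(data=sphere(radius_mm), affine=aff)

    lo, hi = 0.25, max(float(radius_mm), 2.0 * max(spec.voxel_dims))
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = sphere(mid)
        ov = overlap(m)
        if abs(ov - target_tract_overlap) <= tol and m.sum() > 0:
            best = m
            break
        # overlap decreases as the lesion grows beyond the tract
        if ov > target_tract_overlap:
            lo = mid
        else:
            hi = mid
    if best is None:
        raise ValueError("unreachable overlap target for this center")
    return BinaryMask(data=best, affine=aff)


def _motion_table(rng, t):
    steps = rng.normal(scale=[0.02, 0.02, 0.02, 0.002, 0.002, 0.002], size=(t, 6))
    return np.cumsum(steps, axis=0)


def simulate_bold(anatomy, coupling=None, t=150, tr=2.3):
    """BOLD run with planted latent-factor connectivity; returns
    (BoldRun, motion table).

    Each brain voxel's series is the baseline plus ROI latents weighted
    by the ROI probability at that voxel, a global latent over grey
    matter, tissue-specific CSF/WM fluctuations, a slow sinusoidal
    drift, a linear admixture of the motion parameters, and white noise.
    """
    coupling = coupling or CouplingSpec()
    if t < 30:
        raise ValueError("need at least 30 volumes")
    rng = np.random.default_rng(coupling.seed)
    spec = anatomy.spec
    shape = spec.shape

    pair_names = sorted(coupling.inter_coupling)
    shared = {p: rng.standard_normal(t) for p in pair_names}
    hemi = {"left": rng.standard_normal(t), "right": rng.standard_normal(t)}
    glob = rng.standard_normal(t)
    a = coupling.intra_coupling
    latents = {}
    for p in pair_names:
        c = coupling.inter_coupling[p]
        for side in ("left", "right"):
            priv = rng.standard_normal(t)
            rest = np.sqrt(a) * hemi[side] + np.sqrt(1.0 - a) * priv
            latents[f"{p}_{side}"] = np.sqrt(c) * shared[p] + np.sqrt(1.0 - c) * rest

    motion = _motion_table(rng, t)
    leak_mix = rng.normal(size=6)
    drift = coupling.drift_amplitude * np.sin(
        2.0 * np.pi * np.arange(t) * tr / coupling.drift_period_s
    )
    csf_sig = coupling.csf_amplitude * rng.standard_normal(t)
    wm_sig = coupling.wm_amplitude * rng.standard_normal(t)

    brain = anatomy.brain.data > 0
    n_vox = int(brain.sum())
    data = np.zeros(shape + (t,))
    series = np.broadcast_to(coupling.baseline + drift, (n_vox, t)).copy()
    gm_w = anatomy.tissue["gm"].data[brain]
    series += np.outer(gm_w * coupling.global_amplitude, glob)
    series += np.outer(anatomy.tissue["csf"].data[brain], csf_sig)
    series += np.outer(anatomy.tissue["wm"].data[brain], wm_sig)
    for key, lat in latents.items():
        w = anatomy.rois[key].data[brain]
        series += coupling.signal_amplitude * np.outer(w, lat)
    gains = rng.uniform(0.5, 1.5, size=n_vox)
    series += coupling.motion_leak * np.outer(gains, motion @ leak_mix)
    series += coupling.noise_sd * rng.standard_normal((n_vox, t))
    data[brain] = series
    run = BoldRun(data=data, tr=tr, affine=anatomy.brain.affine)
    return run, motion


def planted_pair_correlation(anatomy, coupling, pair, roi_threshold=0.10):
    """Closed-form correlation of the left/right ROI-mean series for a
    homotopic pair under the generative model, assuming the drift and
    motion-leak terms are zero.

    The ROI-mean series is a linear combination of every coupled pair's
    latents (ROI bumps overlap, so a seed mask carries loadings from its
    neighbours too), the global latent, CSF/WM fluctuations and averaged
    white noise; all have known variances and correlations, so the
    correlation of the two means follows exactly from the latent
    correlation matrix.
    """
    pairs = sorted(coupling.inter_coupling)
    sides = ("left", "right")
    keys = [(q, s) for q in pairs for s in sides]
    a = coupling.intra_coupling
    rho = np.eye(len(keys))
    for i, (qi, si) in enumerate(keys):
        for j, (qj, sj) in enumerate(keys):
            if i == j:
                continue
            ci, cj = coupling.inter_coupling[qi], coupling.inter_coupling[qj]
            if qi == qj:
                rho[i, j] = ci
            elif si == sj:
                rho[i, j] = np.sqrt((1 - ci) * (1 - cj)) * a
            else:
                rho[i, j] = 0.0
    A = coupling.signal_amplitude

    def loadings(side):
        mask = anatomy.roi_mask(f"{pair}_{side}", roi_threshold).data > 0
        w = np.array([A * anatomy.rois[f"{q}_{s}"].data[mask].mean()
                      for q, s in keys])
        extra = np.array([
            coupling.global_amplitude * anatomy.tissue["gm"].data[mask].mean(),
            anatomy.tissue["csf"].data[mask].mean(),
            anatomy.tissue["wm"].data[mask].mean(),
        ])
        return w, extra, int(mask.sum())

    wL, eL, nL = loadings("left")
    wR, eR, nR = loadings("right")
    amp2 = np.array([1.0, coupling.csf_amplitude**2, coupling.wm_amplitude**2])
    s2 = coupling.noise_sd**2
    cov = wL @ rho @ wR + (amp2 * eL * eR).sum()
    var_l = wL @ rho @ wL + (amp2 * eL * eL).sum() + s2 / nL
    var_r = wR @ rho @ wR + (amp2 * eR * eR).sum() + s2 / nR
    return cov / np.sqrt(var_l * var_r)


def simulate_cohort(spec=None):
    """Synthetic marker/outcome table from the stated linear models."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    lesion = rng.uniform(*spec.lesion_range, size=n)
    li_s1 = rng.uniform(*spec.li_range, size=n)
    li_m1 = np.clip(li_s1 + rng.normal(scale=0.15, size=n), -1, 1)
    wcst = np.clip(
        spec.wcst_fraction * lesion + rng.normal(scale=0.05 * lesion.mean(), size=n),
        0.0, None,
    )
    rows = {
        "id": [f"P{i+1:02d}" for i in range(n)],
        "group": ["stroke"] * n,
        "lesion_volume": lesion,
        "wcst_ll": wcst,
        "li_s1": li_s1,
        "li_m1": li_m1,
    }
    for outcome, c in spec.coefficients.items():
        y = (
            c["intercept"]
            + c["beta_lesion"] * lesion
            + c["beta_li"] * li_s1
            + (rng.normal(scale=c["noise_sd"], size=n) if c["noise_sd"] > 0 else 0.0)
        )
        if outcome == "nihss":
            y = np.clip(y, 0.0, None)
        else:
            y = np.clip(y, 1.0, 7.0)
        rows[outcome] = y
    table = pd.DataFrame(rows)
    for i in range(spec.n_controls):
        table.loc[len(table)] = {
            "id": f"C{i+1:02d}", "group": "control",
            "lesion_volume": 0.0, "wcst_ll": 0.0,
            "li_s1": np.nan, "li_m1": np.nan,
            **{k: np.nan for k in spec.coefficients},
        }
    for row_idx, col in spec.missing:
        table.loc[row_idx, col] = np.nan
    return table
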