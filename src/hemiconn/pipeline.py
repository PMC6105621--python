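"""Per-subject and cohort orchestration.

``run_subject`` applies the fixed stage order — mirror (if the lesion is
on the non-configured side), steady-state discard, grand-mean
normalization, spatial smoothing, temporal high-pass, nuisance assembly,
lesion exclusion, seed construction, per-seed GLM + GRF thresholding,
laterality, lesion load — and returns one marker row per subject.
``run_cohort`` stacks marker rows, fits the group maps per seed and
group, and produces the correlation and hierarchical-regression
reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    BinaryMask,
    discard_initial,
    extract_tissue_ts,
    gaussian_smooth,
    grand_mean_normalize,
    highpass_gaussian_line,
    mask_stats,
    mirror_lr,
)
from .fc import (
    NuisanceMatrix,
    SeedSpec,
    build_seed_mask,
    estimate_smoothness,
    fc_glm,
    grf_cluster_threshold,
    group_glm,
    seed_timeseries,
)
from .laterality import laterality_index
from .lesion import apply_lesion_exclusion, wcst_ll
from .stats import correlation_report, hierarchical_regression

__all__ = ["RunConfig", "SubjectData", "run_subject", "run_cohort"]

DEFAULT_MARKERS = ["lesion_volume", "wcst_ll", "li_s1", "li_m1"]
DEFAULT_OUTCOMES = ["nihss", "chedoke_arm", "chedoke_hand",
                    "chedoke_foot", "chedoke_leg"]


@dataclass
class RunConfig:
    discard_k: int = 5
    grand_mean: float = 10000.0
    smoothing_fwhm_mm: float = 6.0
    highpass_sigma_s: float = 100.0
    tissue_threshold: float = 0.80
    seed_threshold: float = 0.10
    subject_z_thr: float = 2.3
    group_z_thr: float = 3.0
    alpha: float = 0.05
    affected_side: str = "left"   # images are mirrored so lesions sit here
    li_input: str = "surviving"   # or "voxelwise"
    wcst_weighting: str = "linear"
    wcst_tract_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self):
        checks = [
            0 <= self.discard_k,
            self.grand_mean > 0,
            self.smoothing_fwhm_mm >= 0,
            self.highpass_sigma_s > 0,
            0 < self.tissue_threshold < 1,
            0 < self.seed_threshold < 1,
            self.subject_z_thr > 0,
            self.group_z_thr > 0,
            0 < self.alpha < 1,
            self.affected_side in ("left", "right"),
            self.li_input in ("surviving", "voxelwise"),
            self.wcst_weighting in ("linear", "squared"),
        ]
        if not all(checks):
            raise ValueError("config value outside its documented range")

    def to_json(self):
        return json.dumps({**asdict(self), "version": __version__},
                          indent=2, sort_keys=True)


@dataclass
class SubjectData:
    """One subject's aligned inputs (already on a common grid)."""

    subject_id: str
    bold: object                 # BoldRun
    motion: np.ndarray           # t x 6 (pre- or post-discard rows)
    rois: dict                   # e.g. 's1_left' -> ProbMap
    tissue: dict                 # 'csf'/'wm'/'gm' -> ProbMap
    brain: BinaryMask
    tract: object = None         # ProbMap, optional
    lesion: BinaryMask = None
    lesion_side: str = None      # 'left'/'right'; triggers mirroring
    group: str = "stroke"
    clinical: dict = field(default_factory=dict)


def _maybe_mirror(sub, cfg, log):
    """Mirror all images once at ingest if the lesion is on the wrong side."""
    if sub.lesion_side is None or sub.lesion_side == cfg.affected_side:
        return sub, False
    log.append(f"mirroring images: lesion on {sub.lesion_side}, "
               f"configured affected side {cfg.affected_side}")
    mirrored = SubjectData(
        subject_id=sub.subject_id,
        bold=mirror_lr(sub.bold),
        motion=sub.motion,
        rois={k: mirror_lr(v) for k, v in sub.rois.items()},
        tissue={k: mirror_lr(v) for k, v in sub.tissue.items()},
        brain=mirror_lr(sub.brain),
        tract=mirror_lr(sub.tract) if sub.tract is not None else None,
        lesion=mirror_lr(sub.lesion) if sub.lesion is not None else None,
        lesion_side=cfg.affected_side,
        group=sub.group,
        clinical=sub.clinical,
    )
    # left ROIs are now on the affected side; swap the side labels
    swapped = {}
    for k, v in mirrored.rois.items():
        if k.endswith("_left"):
            swapped[k[:-5] + "_right"] = v
        elif k.endswith("_right"):
            swapped[k[:-6] + "_left"] = v
        else:
            swapped[k] = v
    mirrored.rois = swapped
    return mirrored, True


def run_subject(cfg, sub):
    """Run the full per-subject pipeline; returns an artifact dict.

    Artifacts: preprocessed run, per-seed FCMap / ClusterTable /
    surviving mask, laterality results, lesion markers and one marker
    row (pd.Series).  Any stage error is re-raised annotated with the
    stage name.
    """
    log = []
    stage = "ingest"
    try:
        sub, mirrored = _maybe_mirror(sub, cfg, log)

        stage = "discard"
        bold = discard_initial(sub.bold, cfg.discard_k)
        motion = np.asarray(sub.motion, dtype=float)
        if motion.shape[0] == sub.bold.n_volumes:
            motion = motion[cfg.discard_k:]
        if motion.shape[0] != bold.n_volumes:
            raise ValueError("motion rows do not match retained volumes")

        stage = "grand-mean normalization"
        bold = grand_mean_normalize(bold, sub.brain, cfg.grand_mean)

        stage = "smoothing"
        bold = gaussian_smooth(bold, cfg.smoothing_fwhm_mm)

        stage = "high-pass"
        bold = highpass_gaussian_line(bold, cfg.highpass_sigma_s)

        stage = "nuisance assembly"
        csf_ts, wm_ts, _ = extract_tissue_ts(
            bold, sub.tissue["csf"], sub.tissue["wm"], sub.tissue["gm"],
            cfg.tissue_threshold,
        )
        global_ts = bold.data[sub.brain.data > 0].mean(axis=0)
        nuis = NuisanceMatrix.assemble(csf_ts, wm_ts, global_ts, motion)

        stage = "lesion exclusion"
        analysis_mask = BinaryMask(data=sub.brain.data.copy(), affine=sub.brain.affine)
        if sub.lesion is not None:
            bold = apply_lesion_exclusion(bold, sub.lesion)
            analysis_mask = apply_lesion_exclusion(analysis_mask, sub.lesion)

        stage = "seed masks"
        seeds = {}
        for name in ("s1_left", "s1_right", "m1_left", "m1_right"):
            seed = build_seed_mask(SeedSpec(maps=[sub.rois[name]],
                                            threshold=cfg.seed_threshold,
                                            side=name))
            if sub.lesion is not None:
                seed = apply_lesion_exclusion(seed, sub.lesion)
            seeds[name] = seed

        stage = "seed GLM + GRF"
        fcmaps, tables, surviving = {}, {}, {}
        for name, seed in seeds.items():
            ts = seed_timeseries(bold, seed)
            fcm, resid = fc_glm(bold, ts, nuis, mask=analysis_mask,
                                seed_id=name, subject_id=sub.subject_id)
            sm = estimate_smoothness(resid, analysis_mask)
            table, surv = grf_cluster_threshold(
                fcm, sm, z_thr=cfg.subject_z_thr, alpha=cfg.alpha
            )
            if cfg.li_input == "voxelwise":
                surv_for_li = BinaryMask(
                    data=((fcm.z > cfg.subject_z_thr) & (analysis_mask.data > 0)).astype(float),
                    affine=fcm.affine,
                )
            else:
                surv_for_li = surv
            fcmaps[name], tables[name], surviving[name] = fcm, table, surv_for_li

        stage = "laterality"
        aff, non = cfg.affected_side, ("right" if cfg.affected_side == "left" else "left")
        li = {}
        for pair in ("s1", "m1"):
            roi_ad = seeds[f"{pair}_{aff}"]
            roi_nand = seeds[f"{pair}_{non}"]
            li[pair] = laterality_index(
                surviving[f"{pair}_{aff}"], roi_ad, roi_nand,
                seed_id=f"{pair}_{aff}", input_map=cfg.li_input,
            )

        stage = "lesion markers"
        if sub.lesion is not None:
            lesion_volume = mask_stats(sub.lesion)["volume_mm3"]
            wres = (wcst_ll(sub.lesion, sub.tract, cfg.wcst_tract_threshold,
                            cfg.wcst_weighting)
                    if sub.tract is not None else None)
        else:
            lesion_volume, wres = 0.0, None

        row = pd.Series({
            "id": sub.subject_id,
            "group": sub.group,
            "lesion_volume": lesion_volume,
            "wcst_ll": wres.wcst_ll if wres else np.nan,
            "li_s1": li["s1"].li,
            "li_m1": li["m1"].li,
            **sub.clinical,
        })
        log.append(f"{sub.subject_id}: analysis mask "
                   f"{int(analysis_mask.data.sum())} voxels, "
                   f"seed sizes {[int(s.data.sum()) for s in seeds.values()]}")
        return {
            "row": row, "fcmaps": fcmaps, "cluster_tables": tables,
            "surviving": surviving, "laterality": li, "wcst": wres,
            "mirrored": mirrored, "log": log, "config": cfg,
        }
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed for "
                           f"{sub.subject_id}: {err}") from err


def run_cohort(cfg, subject_results,
               markers=DEFAULT_MARKERS, outcomes=DEFAULT_OUTCOMES):
    """Cohort-level artifacts from per-subject results.

    Group Z maps are fitted per seed within each group present; the
    correlation and regression reports are computed over the stroke
    group's marker rows (outcome columns must be present there).
    """
    rows = pd.DataFrame([r["row"] for r in subject_results])
    stroke = [r for r in subject_results if r["row"]["group"] == "stroke"]
    if len(stroke) < 3:
        raise ValueError("need at least 3 stroke subjects")
    groups = sorted({r["row"]["group"] for r in subject_results})
    group_maps = {}
    for g in groups:
        members = [r for r in subject_results if r["row"]["group"] == g]
        if len(members) < 3:
            continue
        for seed_name in members[0]["fcmaps"]:
            maps = [m["fcmaps"][seed_name] for m in members]
            group_maps[(g, seed_name)] = group_glm(
                maps, group_z_thr=cfg.group_z_thr, alpha=cfg.alpha
            )
    stroke_rows = rows[rows["group"] == "stroke"]
    available_outcomes = [o for o in outcomes if o in stroke_rows.columns]
    corr = (correlation_report(stroke_rows, markers, available_outcomes)
            if available_outcomes else None)
    regressions = {}
    for y in available_outcomes:
        try:
            regressions[y] = hierarchical_regression(
                stroke_rows, y, ["lesion_volume"], ["li_s1"]
            )
        except ValueError:
            continue
    return {
        "table": rows, "group_maps": group_maps,
        "correlations": corr, "regressions": regressions, "config": cfg,
    }
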