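# hemiconn

Imaging markers of post-stroke impairment: seed-based resting-state
functional connectivity (rs-FC) with Gaussian-random-field cluster
inference, weighted corticospinal-tract lesion load, an interhemispheric
laterality index, and the cohort statistics that relate these markers to
clinical scores.

After a stroke, connectivity between the lesioned hemisphere's primary
sensory (S1) or motor (M1) cortex and its homotopic counterpart is often
reduced, while intra-hemispheric connectivity is preserved.  This
package implements the analysis chain used to quantify that asymmetry
and relate it — together with anatomical lesion markers — to
neurological (NIHSS) and motor (Chedoke-McMaster) impairment.  It is
aimed at researchers who want the individual stages (preprocessing
primitives, nuisance-regressed seed GLMs, cluster-extent inference,
laterality, hierarchical regression) as tested, composable functions, on
their own data or on fully synthetic phantoms.

## The markers

**Weighted CST lesion load.** For a lesion mask and a probabilistic
corticospinal-tract map on the same grid,

    wCST-LL = Σ_{n=1..n_max} (1/10) · I(n) · v

where the sum runs over the n_max voxels where the lesion intersects the
tract, I(n) is the tract probability of voxel n on the percent scale,
and v is the voxel volume in mm³.  A lesion of k voxels inside a
uniform-probability-p region scores k·(p/10)·v.

**Seed connectivity.** The seed mask is the union of probabilistic ROI
maps thresholded at 10%.  Each voxel's time series is regressed on the
seed's mean series plus nine nuisance regressors (CSF, WM, global
signal, six motion parameters) and an intercept; the seed coefficient's
t statistic is mapped to a Z score.  Residual smoothness (per-axis FWHM,
RESELs) feeds cluster-extent inference on {Z > 2.3} (26-connectivity):

    E[m]    = R · (4 ln 2)^{3/2} (2π)^{-2} (z² − 1) e^{−z²/2}
    P(n≥k)  = exp(−β k^{2/3}),   β = [Γ(5/2) E[m] / E[N]]^{2/3}
    p_FWE   = 1 − exp(−E[m] · P(n ≥ k))

with finite-grid refinements described in `docs/methods.md`.  Group maps
are one-sample OLS GLMs across subject Z maps at Z ≥ 3.

**Laterality index.** With n_AD the surviving-voxel count inside the
affected/dominant homotopic ROI and n_NAND inside the other hemisphere's,

    LI = (n_AD − n_NAND) / (n_AD + n_NAND)  ∈ [−1, 1],

+1 meaning purely intra-hemispheric connectivity, 0 symmetric.

**Cohort statistics.** Marker-outcome Pearson grids with pairwise
deletion, and two-block hierarchical regression with the R²-change
F test and variance inflation factors.

## Worked example

The package bundles the eight-patient worked-example cohort (lesion
volume, wCST-LL, NIHSS, Chedoke-McMaster scores; one missing foot
score):

```python
from hemiconn.datasets import load_stroke_cohort
from hemiconn.stats import correlation_report

t = load_stroke_cohort()
rep = correlation_report(
    t, ["lesion_volume", "wcst_ll"],
    ["nihss", "chedoke_arm", "chedoke_hand", "chedoke_foot", "chedoke_leg"],
)
for (marker, outcome), cell in rep.cells.items():
    print(marker, outcome, round(cell["r"], 3), "n=%d" % cell["n"])
```

prints, among others,

```
lesion_volume nihss 0.816 n=8
lesion_volume chedoke_arm -0.916 n=8
lesion_volume chedoke_foot -0.827 n=7
wcst_ll nihss 0.758 n=8
wcst_ll chedoke_hand -0.773 n=8
```

— larger lesions and heavier tract damage go with worse neurological
scores (NIHSS rises, Chedoke falls), and the foot column's n drops to 7
by pairwise deletion around the missing cell.

A full synthetic subject, from phantom to marker row:

```python
from hemiconn.synth import (CouplingSpec, make_phantom_anatomy,
                            make_lesion, simulate_bold)
from hemiconn.pipeline import RunConfig, SubjectData, run_subject

anatomy = make_phantom_anatomy()
run, motion = simulate_bold(
    anatomy, CouplingSpec(seed=0, inter_coupling={"s1": 0.2, "m1": 0.7}),
    t=150)
sub = SubjectData(subject_id="demo", bold=run, motion=motion,
                  rois=anatomy.rois, tissue=anatomy.tissue,
                  brain=anatomy.brain, tract=anatomy.tract,
                  lesion=make_lesion(anatomy, (9, 14, 10), 9.0))
res = run_subject(RunConfig(), sub)
print(res["row"].to_string())
```

```
id                      demo
group                 stroke
lesion_volume         3321.0
wcst_ll          13440.89864
li_s1                    1.0
li_m1                    0.0
```

The planted S1 interhemispheric coupling is weak (0.2), so the S1 seed's
suprathreshold connectivity stays entirely in the seed's own hemisphere
(LI = 1), while the unimpaired M1 pair is symmetric (LI = 0).

The same stages are scriptable from the shell: `hemiconn simulate`,
`hemiconn wcstll`, `hemiconn fcmap`, `hemiconn group`, `hemiconn li`,
`hemiconn stats correlate` and `hemiconn stats regress` (see
`hemiconn --help`).

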