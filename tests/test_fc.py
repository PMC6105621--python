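"""Seed masks, nuisance GLM, smoothness and GRF cluster inference."""

import numpy as np
import pytest
from scipy import stats as sstats
from scipy.ndimage import gaussian_filter, label

from hemiconn.core import BinaryMask, BoldRun
from hemiconn.fc import (
    FCMap,
    NuisanceMatrix,
    SeedSpec,
    SmoothnessEstimate,
    build_seed_mask,
    estimate_smoothness,
    fc_glm,
    grf_cluster_threshold,
    group_glm,
    label_clusters,
    roi_coverage,
    seed_timeseries,
)

from conftest import make_mask, make_prob


def gaussian_bump(shape, center, sigma=1.5):
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2 * sigma**2))


def random_nuisance(rng, t):
    return NuisanceMatrix(values=rng.normal(size=(t, 9)))


class TestSeedMask:
    def test_union_of_disjoint_bumps_matches_voxel_loop(self):
        shape = (12, 12, 8)
        a = gaussian_bump(shape, (3, 3, 4))
        b = gaussian_bump(shape, (9, 9, 4))
        mask = build_seed_mask(SeedSpec(maps=[make_prob(a), make_prob(b)]))
        expected = ((a >= 0.10) | (b >= 0.10)).astype(float)
        assert np.array_equal(mask.data, expected)

    def test_threshold_one_rejected(self):
        with pytest.raises(ValueError):
            SeedSpec(maps=[make_prob(np.zeros((3, 3, 3)))], threshold=1.0)

    def test_all_subthreshold_is_empty_seed_error(self):
        with pytest.raises(ValueError, match="empty seed mask"):
            build_seed_mask(SeedSpec(maps=[make_prob(np.full((3, 3, 3), 0.05))]))


class TestRoiCoverage:
    def test_full_coverage(self):
        area = make_prob(gaussian_bump((10, 10, 10), (5, 5, 5)))
        mask = make_mask(np.ones((10, 10, 10)))
        assert roi_coverage(mask, area, 0.10) == pytest.approx(100.0)

    def test_disjoint_coverage_zero(self):
        area = make_prob(gaussian_bump((12, 10, 10), (2, 5, 5), sigma=1.0))
        mask_data = np.zeros((12, 10, 10))
        mask_data[9:] = 1.0
        assert roi_coverage(make_mask(mask_data), area, 0.10) == 0.0

    def test_partial_coverage_matches_count_ratio(self):
        shape = (12, 10, 10)
        area = make_prob(gaussian_bump(shape, (6, 5, 5)))
        half = np.zeros(shape)
        half[:6] = 1.0
        support = area.data >= 0.10
        expected = 100.0 * (support & (half > 0)).sum() / support.sum()
        assert roi_coverage(make_mask(half), area, 0.10) == pytest.approx(expected)


class TestSeedTimeseries:
    def test_single_voxel_seed(self, rng):
        run = BoldRun(data=rng.normal(size=(4, 4, 4, 9)), tr=2.0)
        seed = np.zeros((4, 4, 4))
        seed[2, 1, 3] = 1.0
        assert np.array_equal(seed_timeseries(run, make_mask(seed)),
                              run.data[2, 1, 3])

    def test_opposite_series_cancel(self, rng):
        s = rng.normal(size=9)
        data = np.zeros((4, 4, 4, 9))
        data[0, 0, 0] = s
        data[1, 0, 0] = -s
        run = BoldRun(data=data, tr=2.0)
        seed = np.zeros((4, 4, 4))
        seed[:2, 0, 0] = 1.0
        assert np.allclose(seed_timeseries(run, make_mask(seed)), 0.0)

    def test_block_matches_bruteforce_mean(self, rng):
        run = BoldRun(data=rng.normal(size=(5, 5, 5, 7)), tr=2.0)
        sel = rng.uniform(size=(5, 5, 5)) > 0.5
        ts = seed_timeseries(run, make_mask(sel.astype(float)))
        assert np.allclose(ts, run.data[sel].mean(axis=0))


class TestFcGlm:
    def test_perfect_fit_reaches_cap(self, rng):
        t = 60
        nuis = random_nuisance(rng, t)
        seed_ts = rng.normal(size=t)
        data = np.zeros((2, 2, 2, t))
        data[...] = seed_ts
        run = BoldRun(data=data, tr=2.0)
        fc, _ = fc_glm(run, seed_ts, nuis)
        assert np.all(fc.z <= 38.0)
        assert np.all(fc.z > 30.0)

    def test_nuisance_column_absorbed(self, rng):
        t = 200
        nuis = random_nuisance(rng, t)
        seed_ts = rng.normal(size=t)
        data = np.zeros((2, 2, 2, t))
        data[...] = nuis.values[:, 0]
        run = BoldRun(data=data, tr=2.0)
        fc, _ = fc_glm(run, seed_ts, nuis)
        assert np.all(np.abs(fc.z) < 0.5)

    def test_planted_effect_matches_single_voxel_ols(self, rng):
        t = 200
        nuis = random_nuisance(rng, t)
        seed_ts = rng.normal(size=t)
        y = 0.5 * seed_ts + rng.normal(size=t)
        data = np.zeros((2, 2, 2, t))
        data[0, 0, 0] = y
        run = BoldRun(data=data, tr=2.0)
        fc, _ = fc_glm(run, seed_ts, nuis)
        X = np.column_stack([np.ones(t), seed_ts, nuis.values])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = t - X.shape[1]
        s2 = resid @ resid / df
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t_expect = beta[1] / se
        z_expect = -sstats.norm.ppf(sstats.t.sf(t_expect, df))
        assert fc.z[0, 0, 0] == pytest.approx(z_expect, abs=1e-8)
        assert fc.df == df

    def test_nuisance_invariance_of_seed_z(self, rng):
        # adding any linear combination of nuisance columns everywhere
        # must leave the seed Z map unchanged
        t = 80
        nuis = random_nuisance(rng, t)
        seed_ts = rng.normal(size=t)
        data = rng.normal(size=(3, 3, 3, t))
        run = BoldRun(data=data, tr=2.0)
        fc0, _ = fc_glm(run, seed_ts, nuis)
        combo = nuis.values @ rng.normal(size=9)
        run2 = BoldRun(data=data + combo, tr=2.0)
        fc1, _ = fc_glm(run2, seed_ts, nuis)
        assert np.allclose(fc0.z, fc1.z, atol=1e-6)

    def test_rank_deficient_design_rejected(self, rng):
        t = 40
        vals = rng.normal(size=(t, 9))
        vals[:, 1] = vals[:, 0]
        seed_ts = vals[:, 0]
        run = BoldRun(data=rng.normal(size=(2, 2, 2, t)), tr=2.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            fc_glm(run, seed_ts, NuisanceMatrix(values=vals))


class TestSmoothness:
    def test_white_noise_floors_at_one_voxel(self, rng):
        mask = make_mask(np.ones((16, 16, 16)))
        ests = []
        for s in range(20):
            r = np.random.default_rng(s).standard_normal((16, 16, 16, 12))
            ests.append(estimate_smoothness(r, mask).fwhm_vox)
        mean = np.mean(ests, axis=0)
        assert np.all(np.abs(mean - 1.0) < 0.2)

    def test_known_smoothing_recovered(self):
        mask = make_mask(np.ones((20, 20, 20)))
        sigma = 2.0 / np.sqrt(8 * np.log(2))
        ests = []
        for s in range(20):
            r = np.random.default_rng(s).standard_normal((20, 20, 20, 16))
            r = gaussian_filter(r, [sigma] * 3 + [0])
            ests.append(estimate_smoothness(r, mask).fwhm_vox)
        mean = np.mean(ests, axis=0)
        assert np.all(np.abs(mean - 2.0) / 2.0 < 0.25)

    def test_resels_double_with_mask_volume(self, rng):
        r = rng.standard_normal((20, 10, 10, 10))
        half = np.zeros((20, 10, 10))
        half[:10] = 1.0
        full = np.ones((20, 10, 10))
        sm_half = estimate_smoothness(r, make_mask(half))
        sm_full = estimate_smoothness(r, make_mask(full))
        ratio = sm_full.resels / sm_half.resels
        # same white-noise smoothness, double the volume
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_smoothness(np.zeros((5, 5, 5, 4)),
                                make_mask(np.ones((5, 5, 5))))


class TestGrfClusterThreshold:
    def test_all_zero_map_gives_empty_table(self):
        mask = make_mask(np.ones((10, 10, 10)))
        fc = FCMap(z=np.zeros((10, 10, 10)), df=50, mask=mask, affine=mask.affine)
        sm = SmoothnessEstimate.from_fwhm(2.0, 1000)
        table, surv = grf_cluster_threshold(fc, sm, 2.3, 0.05)
        assert len(table) == 0 and surv.voxel_count == 0

    def test_inserted_sphere_is_single_significant_cluster(self):
        shape = (32, 32, 32)
        z = np.zeros(shape)
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        d2 = sum((g - 16.0) ** 2 for g in grids)
        sphere = d2 <= 4.9**2
        z[sphere] = 6.0
        assert 450 < sphere.sum() < 550
        mask = make_mask(np.ones(shape))
        fc = FCMap(z=z, df=100, mask=mask, affine=mask.affine)
        sm = SmoothnessEstimate.from_fwhm(2.0, int(np.prod(shape)))
        table, surv = grf_cluster_threshold(fc, sm, 2.3, 0.05)
        assert len(table) == 1
        assert table.rows[0]["extent"] == int(sphere.sum())
        assert table.rows[0]["p_fwe"] < 0.05
        # flood-fill oracle agrees on the component count
        _, n = label(z > 2.3, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert np.array_equal(surv.data, sphere.astype(float))

    def test_survivors_subset_and_alpha_monotonicity(self, rng):
        shape = (24, 24, 24)
        sigma = 2.0 / np.sqrt(8 * np.log(2))
        z = gaussian_filter(rng.standard_normal(shape), sigma)
        z *= 3.0 / z.std()
        mask = make_mask(np.ones(shape))
        fc = FCMap(z=z, df=100, mask=mask, affine=mask.affine)
        sm = SmoothnessEstimate.from_fwhm(2.0, int(np.prod(shape)))
        _, surv_lo = grf_cluster_threshold(fc, sm, 2.3, 0.01)
        _, surv_hi = grf_cluster_threshold(fc, sm, 2.3, 0.10)
        assert np.all(surv_lo.data <= (z > 2.3))
        assert np.all(surv_lo.data <= surv_hi.data)

    def test_missing_smoothness_rejected(self):
        mask = make_mask(np.ones((5, 5, 5)))
        fc = FCMap(z=np.zeros((5, 5, 5)), df=10, mask=mask, affine=mask.affine)
        with pytest.raises(ValueError, match="smoothness"):
            grf_cluster_threshold(fc, None, 2.3, 0.05)


class TestGroupGlm:
    def _fcmap(self, z, mask):
        return FCMap(z=z, df=50, mask=mask, affine=mask.affine)

    def test_identical_maps_keep_input_sign(self, rng):
        shape = (10, 10, 10)
        mask = make_mask(np.ones(shape))
        base = gaussian_filter(rng.standard_normal(shape), 1.5) * 5
        maps = [self._fcmap(base.copy(), mask) for _ in range(5)]
        fc, _, _ = group_glm(maps)
        nz = np.abs(base) > 1e-6
        assert np.all(np.sign(fc.z[nz]) == np.sign(base[nz]))

    def test_group_t_matches_one_sample_oracle(self, rng):
        shape = (8, 8, 8)
        mask = make_mask(np.ones(shape))
        effect = rng.normal(size=shape)
        stack = [effect + rng.normal(size=shape) for _ in range(6)]
        maps = [self._fcmap(s, mask) for s in stack]
        fc, _, _ = group_glm(maps)
        arr = np.stack(stack, axis=-1)
        t_oracle = arr.mean(-1) / (arr.std(-1, ddof=1) / np.sqrt(6))
        z_oracle = np.sign(t_oracle) * -sstats.norm.ppf(
            sstats.t.sf(np.abs(t_oracle), 5))
        assert np.allclose(fc.z, z_oracle, atol=1e-6)

    def test_two_maps_rejected(self, rng):
        mask = make_mask(np.ones((5, 5, 5)))
        maps = [self._fcmap(rng.normal(size=(5, 5, 5)), mask) for _ in range(2)]
        with pytest.raises(ValueError, match="at least 3"):
            group_glm(maps)


class TestLabelClusters:
    def _table_for(self, z, mask):
        fc = FCMap(z=z, df=50, mask=mask, affine=mask.affine)
        sm = SmoothnessEstimate.from_fwhm(2.0, int(mask.data.sum()))
        table, _ = grf_cluster_threshold(fc, sm, 2.3, 1.0)
        return table

    def test_cluster_inside_one_label(self):
        shape = (12, 12, 12)
        z = np.zeros(shape)
        z[2:5, 2:5, 2:5] = 5.0
        mask = make_mask(np.ones(shape))
        table = self._table_for(z, mask)
        lab = np.zeros(shape)
        lab[:6] = 1.0
        out = label_clusters(table, {"front": make_mask(lab)})
        assert out[0]["overlap_pct"]["front"] == pytest.approx(100.0)
        assert out[0]["peak_label"] == "front"

    def test_straddling_cluster_overlap_fractions(self):
        shape = (12, 12, 12)
        z = np.zeros(shape)
        z[2:7, 2:4, 2:4] = 5.0     # 5x2x2 = 20 voxels spanning the labels
        mask = make_mask(np.ones(shape))
        table = self._table_for(z, mask)
        a = np.zeros(shape)
        a[:5] = 1.0                # covers 3 of the 5 x-slabs = 60%
        b = np.zeros(shape)
        b[5:] = 1.0
        out = label_clusters(table, {"a": make_mask(a), "b": make_mask(b)})
        assert out[0]["overlap_pct"]["a"] == pytest.approx(60.0)
        assert out[0]["overlap_pct"]["b"] == pytest.approx(40.0)

    def test_empty_table_gives_empty_output(self):
        mask = make_mask(np.ones((8, 8, 8)))
        table = self._table_for(np.zeros((8, 8, 8)), mask)
        assert label_clusters(table, {"x": mask}) == []
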