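"""Group inference: design construction, the voxelwise GLM against a
normal-equations oracle, Monte Carlo extent behaviour, cluster extraction
against a flood-fill oracle, and simple-slopes algebra against stratified
OLS and statsmodels."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from riskconn import inference
from riskconn.grid import BrainGrid
from riskconn.rsfc import SeedROI


def _sexes(n_m, n_f):
    return np.array(["male"] * n_m + ["female"] * n_f)


class TestDesign:
    def test_full_rank_and_centered(self, rng):
        g = rng.standard_normal(8)
        d = inference.build_design(g, _sexes(4, 4))
        x = d.to_numpy()
        assert np.linalg.matrix_rank(x) == 4
        assert abs(x[:, 1].mean()) < 1e-12

    def test_single_sex_rejected(self, rng):
        with pytest.raises(ValueError):
            inference.build_design(rng.standard_normal(6), _sexes(6, 0))

    def test_product_column_is_product(self, rng):
        g = rng.standard_normal(10)
        d = inference.build_design(g, _sexes(5, 5)).to_numpy()
        np.testing.assert_allclose(d[:, 3], d[:, 1] * d[:, 2], atol=1e-12)


class TestVoxelwiseGLM:
    def test_exact_linear_fit_gives_huge_t(self, rng):
        n = 24
        g = rng.standard_normal(n)
        sex = _sexes(12, 12)
        design = inference.build_design(g, sex)
        gc = design["grp"].to_numpy()
        maps = (2.0 + 3.0 * gc)[:, None, None, None] * np.ones((n, 2, 2, 1))
        mask = np.ones((2, 2, 1), dtype=bool)
        sm = inference.voxelwise_glm(maps, design, mask)
        assert np.abs(sm.t["grp"][mask]).min() > 1e6
        # the interaction coefficient is exactly zero in the generating
        # model; its t is 0/0 noise under an exact fit, so check the beta
        assert np.abs(sm.beta["grp_x_sex"][mask]).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        n = 5
        g = rng.standard_normal(n)
        sex = _sexes(3, 2)
        design = inference.build_design(g, sex)
        y = rng.standard_normal((n, 1, 1, 1))
        mask = np.ones((1, 1, 1), dtype=bool)
        sm = inference.voxelwise_glm(y, design, mask)
        x = design.to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y[:, 0, 0, 0])
        for j, term in enumerate(inference.TERMS):
            assert sm.beta[term][0, 0, 0] == pytest.approx(beta[j], abs=1e-10)

    def test_interaction_f_is_squared_t(self, rng):
        n = 40
        design = inference.build_design(rng.standard_normal(n), _sexes(20, 20))
        y = rng.standard_normal((n, 3, 2, 1))
        mask = np.ones((3, 2, 1), dtype=bool)
        sm = inference.voxelwise_glm(y, design, mask)
        np.testing.assert_allclose(sm.f_interaction,
                                   sm.t["grp_x_sex"] ** 2, atol=1e-10)
        assert sm.df_resid == n - 4


class TestMCThreshold:
    def test_unsmoothed_sparse_threshold_is_single_voxel(self):
        grid = BrainGrid(dims=(10, 10, 10))
        mask = np.ones(grid.dims, dtype=bool)
        thr = inference.mc_cluster_threshold(
            mask, grid, fwhm=0.0, voxel_p=1e-6, n_iter=200, seed=0)
        assert thr.min_extent_voxels == 1

    def test_looser_voxel_p_needs_larger_extent(self):
        grid = BrainGrid(dims=(16, 16, 12))
        mask = np.ones(grid.dims, dtype=bool)
        loose = inference.mc_cluster_threshold(
            mask, grid, fwhm=6.0, voxel_p=0.005, n_iter=300, seed=3)
        tight = inference.mc_cluster_threshold(
            mask, grid, fwhm=6.0, voxel_p=0.001, n_iter=300, seed=3)
        assert loose.min_extent_voxels >= tight.min_extent_voxels

    def test_more_smoothing_needs_larger_extent(self):
        grid = BrainGrid(dims=(16, 16, 12))
        mask = np.ones(grid.dims, dtype=bool)
        smooth = inference.mc_cluster_threshold(
            mask, grid, fwhm=8.0, voxel_p=0.005, n_iter=300, seed=4)
        rough = inference.mc_cluster_threshold(
            mask, grid, fwhm=3.0, voxel_p=0.005, n_iter=300, seed=4)
        assert smooth.min_extent_voxels >= rough.min_extent_voxels


class TestClusterExtraction:
    def _blob_map(self, grid, blobs, value=10.0):
        vol = np.zeros(grid.dims)
        for sl in blobs:
            vol[sl] = value
        return vol

    def test_empty_suprathreshold_set(self, rng):
        grid = BrainGrid(dims=(8, 8, 8))
        mask = np.ones(grid.dims, dtype=bool)
        out = inference.extract_clusters(
            np.zeros(grid.dims), mask, grid, df=100, voxel_p=0.001)
        assert len(out) == 0

    def test_extent_threshold_drops_small_blob(self):
        grid = BrainGrid(dims=(12, 12, 6))
        mask = np.ones(grid.dims, dtype=bool)
        # one 20-voxel blob, one 5-voxel blob; 513 mm3 = 19 voxels at 3 mm
        vol = self._blob_map(grid, [
            (slice(1, 6), slice(1, 5), slice(1, 2)),   # 5*4*1 = 20 voxels
            (slice(8, 9), slice(1, 6), slice(3, 4)),   # 1*5*1 = 5 voxels
        ])
        out = inference.extract_clusters(
            vol, mask, grid, df=100, voxel_p=0.001, min_extent_mm3=513.0,
            stat="t")
        assert len(out) == 1
        assert out.iloc[0]["size_voxels"] == 20
        assert out.iloc[0]["size_mm3"] == 540.0

    def test_corner_touch_depends_on_adjacency(self):
        grid = BrainGrid(dims=(8, 8, 4))
        mask = np.ones(grid.dims, dtype=bool)
        vol = self._blob_map(grid, [
            (slice(1, 3), slice(1, 3), slice(1, 2)),
            (slice(3, 5), slice(3, 5), slice(2, 3)),  # touches at a corner
        ])
        got26 = inference.extract_clusters(
            vol, mask, grid, df=50, voxel_p=0.01, min_extent_mm3=27.0,
            adjacency=26)
        got6 = inference.extract_clusters(
            vol, mask, grid, df=50, voxel_p=0.01, min_extent_mm3=27.0,
            adjacency=6)
        assert len(got26) == 1 and len(got6) == 2

    def test_matches_flood_fill_oracle(self, rng):
        grid = BrainGrid(dims=(10, 10, 10))
        mask = np.ones(grid.dims, dtype=bool)
        vol = rng.standard_normal(grid.dims) * 3
        df = 60
        voxel_p = 0.05
        thr = stats.t.isf(voxel_p / 2, df)
        out = inference.extract_clusters(
            vol, mask, grid, df=df, voxel_p=voxel_p, min_extent_mm3=27.0,
            adjacency=6, stat="t")
        labels, n = ndimage.label(np.abs(vol) > thr,
                                  structure=ndimage.generate_binary_structure(3, 1))
        sizes = sorted(np.bincount(labels.ravel())[1:], reverse=True)
        assert sorted(out["size_voxels"], reverse=True) == [s for s in sizes if s >= 1]

    def test_peak_inside_cluster_with_world_coordinates(self):
        grid = BrainGrid(dims=(9, 9, 9))
        mask = np.ones(grid.dims, dtype=bool)
        vol = np.zeros(grid.dims)
        vol[4, 4, 4] = 50.0
        vol[4, 4, 5] = 30.0
        out = inference.extract_clusters(
            vol, mask, grid, df=50, voxel_p=0.01, min_extent_mm3=27.0, stat="F")
        assert len(out) == 1
        world = grid.voxel_to_world(np.array([4, 4, 4]))[0]
        assert (out.iloc[0][["peak_x", "peak_y", "peak_z"]].to_numpy()
                == world).all()
        assert out.iloc[0]["peak_stat"] == 50.0


class TestROIAverage:
    def test_single_voxel_identity(self, rng):
        maps = rng.standard_normal((5, 3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        roi = SeedROI("v", np.array([(1, 2, 0)]))
        np.testing.assert_allclose(
            inference.roi_average(maps, roi, mask), maps[:, 1, 2, 0])

    def test_matches_sum_count_oracle(self, rng):
        maps = rng.standard_normal((4, 5, 5, 2))
        mask = np.ones((5, 5, 2), dtype=bool)
        vox = np.array([(x, y, z) for x in range(3) for y in range(2)
                        for z in range(2)])
        roi = SeedROI("r", vox)
        oracle = np.array([m[tuple(vox.T)].mean() for m in maps])
        np.testing.assert_allclose(
            inference.roi_average(maps, roi, mask), oracle, atol=1e-12)


class TestSimpleSlopes:
    def test_equal_slopes_null_interaction(self):
        g = np.r_[-1.5, -0.5, 0.5, 1.5, -1.5, -0.5, 0.5, 1.5]
        sex = _sexes(4, 4)
        rng = np.random.default_rng(6)
        y = 2.0 * g + 0.1 * rng.standard_normal(8)  # same slope both sexes
        s = inference.probe_interaction(y, g, sex)
        assert abs(s.interaction_t) < 3.0  # no systematic interaction
        exact = inference.probe_interaction(2.0 * g, g, sex)
        assert exact.interaction_coef == pytest.approx(0.0, abs=1e-10)
        assert exact.slope_male == pytest.approx(exact.slope_female, abs=1e-10)

    def test_matches_stratified_ols_oracle(self, rng):
        g = rng.standard_normal(8)
        sex = _sexes(4, 4)
        y = rng.standard_normal(8)
        s = inference.probe_interaction(y, g, sex)
        gc = g - g.mean()
        for label, slope in [("male", s.slope_male), ("female", s.slope_female)]:
            sel = sex == label
            x = np.column_stack([np.ones(sel.sum()), gc[sel]])
            beta = np.linalg.solve(x.T @ x, x.T @ y[sel])
            assert slope == pytest.approx(beta[1], abs=1e-10)

    def test_slope_difference_equals_interaction_coefficient(self, rng):
        g = rng.standard_normal(30)
        sex = _sexes(15, 15)
        y = 0.5 * g + rng.standard_normal(30)
        s = inference.probe_interaction(y, g, sex)
        assert s.slope_male - s.slope_female == pytest.approx(
            s.interaction_coef, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        g = rng.standard_normal(40)
        sex = _sexes(22, 18)
        y = 0.3 * g + 0.4 * (sex == "male") + rng.standard_normal(40)
        ours = inference.probe_interaction(y, g, sex)
        x = inference.build_design(g, sex).to_numpy()
        fit = sm.OLS(y, x).fit()
        assert ours.slope_female == pytest.approx(fit.params[1], abs=1e-10)
        assert ours.interaction_coef == pytest.approx(fit.params[3], abs=1e-10)
        assert ours.interaction_p == pytest.approx(fit.pvalues[3], abs=1e-10)
        assert ours.se_female == pytest.approx(fit.bse[1], abs=1e-10)

    def test_too_few_per_sex_rejected(self, rng):
        with pytest.raises(ValueError):
            inference.probe_interaction(
                rng.standard_normal(5), rng.standard_normal(5), _sexes(2, 3))

    def test_planted_slopes_recovered_within_two_se(self):
        # published-scale conditions: n = 289, slopes +0.11 (M) / -0.08 (F)
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            sex = _sexes(131, 158)
            g = rng.standard_normal(289)
            male = sex == "male"
            y = np.where(male, 0.11 * g, -0.08 * g) + 0.3 * rng.standard_normal(289)
            s = inference.probe_interaction(y, g, sex)
            hits += abs(s.slope_male - 0.11) < 2 * s.se_male
            hits += abs(s.slope_female + 0.08) < 2 * s.se_female
        # each slope's 2-SE interval covers its planted value ~95% of the
        # time; 0.85 leaves Monte Carlo headroom at 60 checks
        assert hits / (2 * n_seeds) >= 0.85
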