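"""Cluster labeling and permutation FWE / small-volume correction."""

from collections import deque

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from imagerylink import glm, inference, volumes
from imagerylink.errors import EmptyMaskError, ValidationError


def flood_fill_clusters(binary, connectivity):
    """Independent BFS flood-fill oracle for connected components."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    coords = np.argwhere(binary)
    for start in map(tuple, coords):
        if seen[start]:
            continue
        queue, size = deque([start]), 0
        seen[start] = True
        while queue:
            p = queue.popleft()
            size += 1
            for off in offsets:
                q = tuple(np.add(p, off))
                if all(0 <= q[d] < binary.shape[d] for d in range(3)):
                    if binary[q] and not seen[q]:
                        seen[q] = True
                        queue.append(q)
        sizes.append(size)
    return sorted(sizes, reverse=True)


def stat_map_from(values, grid, df=20):
    mask = np.ones(grid.shape, bool)
    return glm.StatMap(grid, values.astype(float), "t", df, mask)


class StubEngine:
    """Engine whose permutation distribution is fixed, for exact p checks."""

    kind = "t"

    def __init__(self, grid, observed, permuted_values):
        self.grid = grid
        self.mask = np.ones(grid.shape, bool)
        self.df = 20
        self._obs = observed.ravel()
        self._perm = [p.ravel() for p in permuted_values]
        self._i = 0

    def observed(self):
        return self._obs

    def permuted(self, rng):
        out = self._perm[self._i % len(self._perm)]
        self._i += 1
        return out

    def n_distinct_permutations(self):
        return float("inf")


def make_glm_inputs(rng, n=14, shape=(10, 10, 10), smooth=0.0):
    grid = volumes.VoxelGrid.isotropic(shape, 2.0)
    cohort = pd.DataFrame(
        {
            "interest": rng.standard_normal(n),
            "c1": rng.standard_normal(n),
            "c2": rng.standard_normal(n),
        }
    )
    design = glm.build_design(cohort, "interest", nuisances=("c1", "c2"))
    data = rng.standard_normal((n, *shape))
    if smooth:
        data = np.stack([ndimage.gaussian_filter(d, smooth) for d in data])
    maps = [volumes.VolumeMap(grid, d) for d in data]
    return maps, design, grid


class TestLabelClusters:
    def test_single_constructed_blob(self, grid2mm):
        df = 20
        cutoff = inference.stat_cutoff(0.005, "t", df)
        values = np.zeros(grid2mm.shape)
        values[5:8, 5:9, 5:7] = cutoff + 1.0
        table = inference.label_clusters(stat_map_from(values, grid2mm), 0.005)
        assert len(table) == 1
        assert int(table.table["size"].iloc[0]) == 3 * 4 * 2
        assert table.table["peak_stat"].iloc[0] == pytest.approx(cutoff + 1.0)

    def test_two_blobs_with_subthreshold_gap(self, grid2mm):
        cutoff = inference.stat_cutoff(0.005, "t", 20)
        values = np.zeros(grid2mm.shape)
        values[2:4, 2:4, 2:4] = cutoff + 1
        values[10:13, 10:13, 10:13] = cutoff + 2
        table = inference.label_clusters(stat_map_from(values, grid2mm), 0.005)
        assert sorted(table.table["size"]) == [8, 27]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_maps_match_flood_fill_oracle(self, rng, connectivity):
        grid = volumes.VoxelGrid.isotropic((9, 9, 9), 2.0)
        values = rng.standard_normal(grid.shape) * 2.5
        table = inference.label_clusters(
            stat_map_from(values, grid), 0.05, connectivity=connectivity
        )
        cutoff = inference.stat_cutoff(0.05, "t", 20)
        oracle = flood_fill_clusters(values > cutoff, connectivity)
        assert sorted(table.table["size"], reverse=True) == oracle

    def test_no_suprathreshold_voxels_gives_empty_table(self, grid2mm):
        table = inference.label_clusters(stat_map_from(np.zeros(grid2mm.shape), grid2mm))
        assert len(table) == 0

    def test_peak_coordinate_lies_inside_cluster(self, rng):
        grid = volumes.VoxelGrid.isotropic((9, 9, 9), 2.0)
        values = rng.standard_normal(grid.shape) * 3
        table = inference.label_clusters(stat_map_from(values, grid), 0.05)
        cutoff = inference.stat_cutoff(0.05, "t", 20)
        for _, row in table.table.iterrows():
            idx = tuple(int(v) for v in grid.world_to_index(
                [row.peak_x_mm, row.peak_y_mm, row.peak_z_mm]))
            assert values[idx] > cutoff
            assert values[idx] == pytest.approx(row.peak_stat)


class TestClusterFwe:
    def test_null_permutation_distribution_gives_p_one_for_observed(self, rng, grid2mm):
        cutoff = inference.stat_cutoff(0.005, "t", 20)
        observed = np.zeros(grid2mm.shape)
        observed[4:6, 4:6, 4:6] = cutoff + 1
        # every "permutation" reproduces the observed map -> all p_fwe = 1
        engine = StubEngine(grid2mm, observed, [observed])
        table = inference.cluster_fwe_engine(engine, n_perm=100, seed=0)
        assert np.allclose(table.table["p_fwe"], 1.0)

    def test_p_monotone_nonincreasing_in_cluster_size(self, rng, grid2mm):
        cutoff = inference.stat_cutoff(0.005, "t", 20)
        observed = np.zeros(grid2mm.shape)
        observed[2:4, 2:4, 2:4] = cutoff + 1       # 8 voxels
        observed[10:14, 10:14, 10:14] = cutoff + 1  # 64 voxels
        perms = []
        rg = np.random.default_rng(0)
        for _ in range(25):
            p = np.zeros(grid2mm.shape)
            k = rg.integers(1, 5)
            p[1 : 1 + k, 1:3, 1:3] = cutoff + 1
            perms.append(p)
        engine = StubEngine(grid2mm, observed, perms)
        table = inference.cluster_fwe_engine(engine, n_perm=100, seed=0)
        t = table.table.sort_values("size")
        assert t["p_fwe"].is_monotonic_decreasing or t["p_fwe"].nunique() == 1

    def test_seeded_runs_are_bit_reproducible(self, rng):
        maps, design, _ = make_glm_inputs(rng, smooth=1.2)
        t1 = inference.cluster_fwe(maps, design, n_perm=120, seed=9)
        t2 = inference.cluster_fwe(maps, design, n_perm=120, seed=9)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_small_cohort_triggers_exhaustive_enumeration(self, rng):
        grid = volumes.VoxelGrid.isotropic((5, 5, 5), 2.0)
        n = 4  # 4! = 24 < n_perm
        cohort = pd.DataFrame({"interest": rng.standard_normal(n)})
        design = glm.build_design(cohort, "interest", nuisances=())
        maps = [volumes.VolumeMap(grid, rng.standard_normal(grid.shape)) for _ in range(n)]
        with pytest.warns(UserWarning, match="exhaustively"):
            table = inference.cluster_fwe(maps, design, n_perm=100, seed=0,
                                          forming_threshold_p=0.2)
        assert table.n_perm == 24
        if len(table):
            assert (table.table["p_fwe"] > 0).all()

    def test_too_few_permutations_rejected(self, rng):
        maps, design, _ = make_glm_inputs(rng)
        with pytest.raises(ValidationError):
            inference.cluster_fwe(maps, design, n_perm=50)


class TestSvcPeakFwe:
    def test_single_voxel_sphere_equals_direct_permutation_oracle(self, rng):
        maps, design, grid = make_glm_inputs(rng)
        center = grid.index_to_world(np.array([4, 5, 6]))
        sphere = volumes.make_sphere_mask(center, 0.0, grid)
        assert sphere.n_voxels == 1
        engine = inference.FreedmanLaneEngine.from_maps(maps, design)
        res = inference.svc_peak_fwe(engine, sphere, n_perm=200, seed=5)
        # oracle: rebuild the null for that voxel with the same seed
        flat = sphere.flat_indices()[0]
        rng2 = np.random.default_rng(5)
        exceed = sum(
            engine.permuted(rng2).reshape(-1)[flat] >= res.peak_stat for _ in range(200)
        )
        assert res.p_fwe == pytest.approx((exceed + 1) / 201)

    def test_whole_mask_sphere_equals_whole_map_peak_fwe(self, rng):
        maps, design, grid = make_glm_inputs(rng, shape=(7, 7, 7))
        sphere = volumes.make_sphere_mask(
            grid.index_to_world(np.array([3, 3, 3])), 100.0, grid
        )
        assert sphere.n_voxels == grid.n_voxels
        engine = inference.FreedmanLaneEngine.from_maps(maps, design)
        res = inference.svc_peak_fwe(engine, sphere, n_perm=150, seed=2)
        obs_peak = engine.observed().max()
        rng2 = np.random.default_rng(2)
        exceed = sum(engine.permuted(rng2).max() >= obs_peak for _ in range(150))
        assert res.peak_stat == pytest.approx(obs_peak)
        assert res.p_fwe == pytest.approx((exceed + 1) / 151)

    def test_observed_peak_below_all_permutation_maxima_gives_p_one(self, grid2mm):
        observed = np.zeros(grid2mm.shape)
        high = np.full(grid2mm.shape, 10.0)
        engine = StubEngine(grid2mm, observed, [high])
        sphere = volumes.make_sphere_mask((0, 0, 0), 6.0, grid2mm)
        res = inference.svc_peak_fwe(engine, sphere, n_perm=100, seed=0)
        assert res.p_fwe == 1.0

    def test_sphere_outside_analysis_mask_rejected(self, rng):
        maps, design, grid = make_glm_inputs(rng)
        mask = np.zeros(grid.shape, bool)
        mask[:3] = True
        engine = inference.FreedmanLaneEngine.from_maps(maps, design, mask=mask)
        sphere = volumes.make_sphere_mask(grid.index_to_world(np.array([8, 8, 8])), 2.0, grid)
        with pytest.raises(EmptyMaskError):
            inference.svc_peak_fwe(engine, sphere, n_perm=100, seed=0)
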