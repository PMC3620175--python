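"""Seed maps, smoothing, cluster labeling, and the Monte Carlo extent threshold."""

import numpy as np
import pytest

from thermoconn import statcore as sc
from thermoconn import synthdata as sd
from thermoconn import voxelmap as vm

GRID = (12, 12, 12)
VOX = (3.0, 3.0, 3.0)
ORIGIN = (0.0, 0.0, 0.0)


def make_volume(values, tr=2.0):
    return vm.VolumeSeries(
        values=values, voxel_size_mm=VOX, origin_world_mm=ORIGIN, tr_seconds=tr
    )


class TestSphereRoi:
    def test_radius_zero_at_voxel_center(self):
        mask = vm.sphere_roi_mask(GRID, VOX, ORIGIN, (9.0, 9.0, 9.0), 0.0)
        assert mask.sum() == 1
        assert mask[3, 3, 3]

    def test_count_matches_exhaustive_distance_scan(self):
        center, radius = (15.0, 15.0, 15.0), 10.0
        mask = vm.sphere_roi_mask(GRID, VOX, ORIGIN, center, radius)
        count = 0
        for i in range(GRID[0]):
            for j in range(GRID[1]):
                for k in range(GRID[2]):
                    d2 = sum((3.0 * v - c) ** 2 for v, c in zip((i, j, k), center))
                    count += d2 <= radius**2
        assert mask.sum() == count

    def test_reflection_symmetry_about_center(self):
        mask = vm.sphere_roi_mask(GRID, VOX, ORIGIN, (16.5, 16.5, 16.5), 9.0)
        assert np.array_equal(mask, mask[::-1, ::-1, ::-1])

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            vm.sphere_roi_mask(GRID, VOX, ORIGIN, (200.0, 0.0, 0.0), 5.0)


class TestRoiMeanSeries:
    def test_single_voxel_mask(self, rng):
        vol = make_volume(rng.normal(size=(10,) + GRID))
        mask = np.zeros(GRID, dtype=bool)
        mask[2, 3, 4] = True
        assert np.array_equal(vm.roi_mean_series(vol, mask), vol.values[:, 2, 3, 4])

    def test_two_voxel_mask_is_arithmetic_mean(self, rng):
        vol = make_volume(rng.normal(size=(10,) + GRID))
        mask = np.zeros(GRID, dtype=bool)
        mask[0, 0, 0] = mask[5, 5, 5] = True
        expected = (vol.values[:, 0, 0, 0] + vol.values[:, 5, 5, 5]) / 2.0
        assert np.allclose(vm.roi_mean_series(vol, mask), expected)

    def test_empty_mask_rejected(self, rng):
        vol = make_volume(rng.normal(size=(5,) + GRID))
        with pytest.raises(ValueError, match="empty"):
            vm.roi_mean_series(vol, np.zeros(GRID, dtype=bool))


class TestSeedCorrelationMap:
    def test_self_correlation_saturates_at_max_z(self, rng):
        vol = make_volume(rng.normal(size=(30,) + GRID))
        seed = vol.values[:, 4, 4, 4].copy()
        vol.values[:, 5, 5, 5] = -seed
        zmap = vm.seed_correlation_map(vol, seed)
        zmax = sc.fisher_z(1.0)
        assert zmap.values[4, 4, 4] == pytest.approx(zmax, abs=1e-9)
        assert zmap.values[5, 5, 5] == pytest.approx(-zmax, abs=1e-9)

    def test_matches_scalar_kernel_voxelwise(self, rng):
        vol = make_volume(rng.normal(size=(20, 3, 3, 3)))
        seed = rng.normal(size=20)
        zmap = vm.seed_correlation_map(vol, seed)
        for idx in np.ndindex(3, 3, 3):
            r = sc.pearson_corr(seed, vol.values[(slice(None),) + idx]).statistic
            assert zmap.values[idx] == pytest.approx(sc.fisher_z(r), abs=1e-10)

    def test_constant_voxels_flagged_not_fatal(self, rng):
        vol = make_volume(rng.normal(size=(15,) + GRID))
        vol.values[:, 1, 1, 1] = 3.0
        zmap = vm.seed_correlation_map(vol, rng.normal(size=15))
        assert zmap.values[1, 1, 1] == 0.0
        assert zmap.constant_voxels[1, 1, 1]

    def test_constant_seed_rejected(self, rng):
        vol = make_volume(rng.normal(size=(15,) + GRID))
        with pytest.raises(ValueError, match="constant seed"):
            vm.seed_correlation_map(vol, np.ones(15))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        v = rng.normal(size=GRID)
        assert np.array_equal(vm.smooth_gaussian(v, 0.0, VOX), v)

    def test_impulse_profile_matches_closed_form(self):
        v = np.zeros((15, 15, 15))
        v[7, 7, 7] = 1.0
        fwhm = 6.0
        out = vm.smooth_gaussian(v, fwhm, VOX)
        sigma_vox = fwhm * vm.FWHM_TO_SIGMA / 3.0
        for k in (1, 2):
            expected = np.exp(-(k**2) / (2 * sigma_vox**2))
            ratio = out[7 + k, 7, 7] / out[7, 7, 7]
            assert ratio == pytest.approx(expected, rel=0.01)

    def test_mass_conserved(self, rng):
        v = rng.normal(size=GRID) + 5.0
        out = vm.smooth_gaussian(v, 8.0, VOX)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            vm.smooth_gaussian(rng.normal(size=GRID), -1.0, VOX)


class TestLabelClusters:
    def test_single_voxel(self):
        m = np.zeros(GRID, dtype=bool)
        m[2, 2, 2] = True
        clusters = vm.label_clusters(m, 26)
        assert len(clusters) == 1 and len(clusters[0]) == 1

    def test_face_adjacency_joined_under_all_connectivities(self):
        m = np.zeros(GRID, dtype=bool)
        m[2, 2, 2] = m[2, 2, 3] = True
        for conn in (6, 18, 26):
            assert len(vm.label_clusters(m, conn)) == 1

    def test_corner_adjacency_depends_on_connectivity(self):
        m = np.zeros(GRID, dtype=bool)
        m[2, 2, 2] = m[3, 3, 3] = True
        assert len(vm.label_clusters(m, 6)) == 2
        assert len(vm.label_clusters(m, 18)) == 2
        assert len(vm.label_clusters(m, 26)) == 1

    def test_ordering_largest_first(self):
        m = np.zeros(GRID, dtype=bool)
        m[0:3, 0, 0] = True
        m[6, 6, 6] = True
        clusters = vm.label_clusters(m, 6)
        assert [len(c) for c in clusters] == [3, 1]


class TestAlphaSim:
    MASK = np.ones((14, 14, 14), dtype=bool)

    def test_tiny_voxel_p_needs_single_voxel(self):
        k = vm.alphasim_min_cluster(
            self.MASK.shape, VOX, self.MASK, voxel_p=1e-9,
            n_iterations=200, seed=1,
        )
        assert k == 1

    def test_extent_nondecreasing_in_fwhm(self):
        ks = [
            vm.alphasim_min_cluster(
                self.MASK.shape, VOX, self.MASK, fwhm_mm=f,
                n_iterations=300, seed=2,
            )
            for f in (0.0, 4.0, 8.0)
        ]
        assert ks == sorted(ks)

    def test_reproducible_at_fixed_seed(self):
        args = dict(n_iterations=200, seed=3)
        a = vm.alphasim_min_cluster(self.MASK.shape, VOX, self.MASK, **args)
        b = vm.alphasim_min_cluster(self.MASK.shape, VOX, self.MASK, **args)
        assert a == b

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            vm.alphasim_min_cluster(
                self.MASK.shape, VOX, np.zeros_like(self.MASK), n_iterations=100
            )


class TestGroupVoxelTtest:
    @staticmethod
    def maps_from(volumes):
        out = []
        for vol in volumes:
            sphere = vm.sphere_roi_mask(
                vol.grid_shape, vol.voxel_size_mm, vol.origin_world_mm, (-2, -54, 27), 10
            )
            out.append(vm.seed_correlation_map(vol, vm.roi_mean_series(vol, sphere)))
        return out

    def test_huge_min_cluster_yields_no_records(self, rng):
        maps = [
            vm.ZMap(rng.normal(size=GRID) * 0.01, np.ones(GRID, bool),
                    np.array(VOX), np.array(ORIGIN))
            for _ in range(4)
        ]
        rule = vm.ClusterRule(min_cluster_voxels=10_000)
        _, recs = vm.group_voxel_ttest(maps, None, rule)
        assert recs == []

    def test_min_cluster_one_reduces_to_voxel_test(self, rng):
        maps = [
            vm.ZMap(rng.normal(0.1, 0.2, size=GRID), np.ones(GRID, bool),
                    np.array(VOX), np.array(ORIGIN))
            for _ in range(5)
        ]
        rule = vm.ClusterRule(min_cluster_voxels=1)
        t_map, recs = vm.group_voxel_ttest(maps, None, rule)
        stack = np.stack([m.values for m in maps]).reshape(5, -1)
        _, _, p = sc.one_sample_t_array(stack)
        expected = int((p < rule.voxel_p).sum())
        assert sum(r.extent_voxels for r in recs) == expected

    def test_planted_block_recovered_as_single_cluster(self):
        ht = self.maps_from(
            sd.simulate_voxel_bold(T=100, seed=200 + s, coupling=1.0, block_coupling=1.0)
            for s in range(6)
        )
        nc = self.maps_from(
            sd.simulate_voxel_bold(T=100, seed=300 + s, coupling=1.0, block_coupling=0.0)
            for s in range(6)
        )
        rule = vm.ClusterRule(min_cluster_voxels=30)
        t_map, recs = vm.group_voxel_ttest(ht, nc, rule)
        assert len(recs) == 1
        assert recs[0].direction == "increase"
        block = np.zeros((26, 31, 26), dtype=bool)
        block[3:9, 4:10, 3:9] = True
        # overlap: suprathreshold increase voxels must cover >= 80% of block
        covered = ((t_map > 0) & block).sum() / block.sum()
        assert covered >= 0.8

    def test_identical_distribution_groups_yield_nothing(self):
        a = self.maps_from(
            sd.simulate_voxel_bold(T=100, seed=400 + s, coupling=1.0, block_coupling=0.0)
            for s in range(5)
        )
        b = self.maps_from(
            sd.simulate_voxel_bold(T=100, seed=500 + s, coupling=1.0, block_coupling=0.0)
            for s in range(5)
        )
        _, recs = vm.group_voxel_ttest(a, b, vm.ClusterRule(min_cluster_voxels=30))
        assert recs == []

    def test_extent_mm3_consistency(self, rng):
        maps = [
            vm.ZMap(rng.normal(0.3, 0.1, size=GRID), np.ones(GRID, bool),
                    np.array(VOX), np.array(ORIGIN))
            for _ in range(4)
        ]
        _, recs = vm.group_voxel_ttest(maps, None, vm.ClusterRule(min_cluster_voxels=1))
        for r in recs:
            assert r.extent_mm3 == pytest.approx(r.extent_voxels * 27.0)
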