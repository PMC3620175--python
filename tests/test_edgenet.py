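"""Parcellation, connectivity matrices, the dual-criterion edge test, N_alt."""

import dataclasses

import numpy as np
import pytest

from thermoconn import edgenet as en
from thermoconn import synthdata as sd
from thermoconn import voxelmap as vm
from thermoconn.preprocess import RegionalSeries, clean_series
from thermoconn.statcore import fisher_z


def series_from(values, tr=2.0):
    values = np.asarray(values, dtype=float)
    return RegionalSeries(
        values=values, tr_seconds=tr, region_ids=np.arange(1, values.shape[1] + 1)
    )


def zmat(values, subject_id="s", group=""):
    values = np.asarray(values, dtype=float)
    return en.ZEdgeMatrix(
        z=values, region_ids=np.arange(1, values.shape[0] + 1),
        subject_id=subject_id, group=group,
    )


class TestParcellate:
    @staticmethod
    def volume(rng, shape=(6, 6, 6), T=10):
        return vm.VolumeSeries(
            values=rng.normal(size=(T,) + shape),
            voxel_size_mm=(3.0, 3.0, 3.0),
            origin_world_mm=(0.0, 0.0, 0.0),
        )

    def test_single_label_gives_global_mean(self, rng):
        vol = self.volume(rng)
        labels = np.ones(vol.grid_shape, dtype=int)
        out = en.parcellate_means(vol, labels)
        assert np.allclose(out.values[:, 0], vol.values.reshape(10, -1).mean(axis=1))

    def test_ninety_labels_give_ninety_columns(self, rng):
        vol = self.volume(rng, shape=(5, 6, 3), T=8)
        labels = np.arange(90).reshape(vol.grid_shape) + 1
        out = en.parcellate_means(vol, labels)
        assert out.n_regions == 90
        assert np.array_equal(out.region_ids, np.arange(1, 91))

    def test_two_voxel_region_hand_mean(self, rng):
        vol = self.volume(rng)
        labels = np.zeros(vol.grid_shape, dtype=int)
        labels[0, 0, 0] = labels[1, 0, 0] = 4
        out = en.parcellate_means(vol, labels)
        expected = (vol.values[:, 0, 0, 0] + vol.values[:, 1, 0, 0]) / 2
        assert np.allclose(out.values[:, 0], expected)

    def test_grid_mismatch_rejected(self, rng):
        vol = self.volume(rng)
        with pytest.raises(ValueError):
            en.parcellate_means(vol, np.ones((2, 2, 2), dtype=int))


class TestConnectivityMatrix:
    def test_ninety_regions_give_4005_edges(self, rng):
        m = en.connectivity_matrix(series_from(rng.normal(size=(50, 90))))
        assert m.edge_vector().size == 4005

    def test_duplicated_columns_saturate_z(self, rng):
        v = rng.normal(size=(30, 3))
        v[:, 2] = v[:, 0]
        m = en.connectivity_matrix(series_from(v))
        assert m.z[0, 2] == pytest.approx(fisher_z(1.0), abs=1e-9)

    def test_symmetry_and_zero_diagonal(self, rng):
        m = en.connectivity_matrix(series_from(rng.normal(size=(40, 8))))
        assert np.array_equal(m.z, m.z.T)
        assert np.all(np.diag(m.z) == 0.0)

    def test_constant_region_named_in_error(self, rng):
        v = rng.normal(size=(30, 4))
        v[:, 2] = 1.0
        with pytest.raises(ValueError, match="3"):
            en.connectivity_matrix(series_from(v))

    def test_converges_to_generator_target(self):
        errs = []
        for T in (200, 2000, 20000):
            d = sd.SimulationDesign(
                n_regions=20, n_volumes_acquired=T, noise_sd=0.0,
                drift_slope_sd=0.0, altered_edges=((1, 4, 0.5),), seed=6,
            )
            s = sd.simulate_regional_bold(d, "HT", 0)
            m = en.connectivity_matrix(s)
            target = fisher_z(sd.make_group_covariance(d, "HT"))
            np.fill_diagonal(target, 0.0)
            errs.append(np.abs(m.z - target).max())
        assert errs[2] < errs[0]
        assert errs[2] < 0.05


class TestDualCriterion:
    @staticmethod
    def sample_groups(rng, n_ht=10, n_nc=10, R=12, shift_edges=()):
        base = fisher_z(0.3)
        mats = {"HT": [], "NC": []}
        for g, n in (("HT", n_ht), ("NC", n_nc)):
            for k in range(n):
                z = base + rng.normal(0, 0.1, (R, R))
                z = (z + z.T) / 2
                if g == "HT":
                    for (i, j, dz) in shift_edges:
                        z[i, j] += dz
                        z[j, i] += dz
                np.fill_diagonal(z, 0)
                mats[g].append(zmat(z, subject_id=f"{g}{k}", group=g))
        return mats

    def test_planted_shift_found_with_correct_direction(self, rng):
        mats = self.sample_groups(rng, shift_edges=((2, 7, 0.8), (3, 9, -0.8)))
        findings = en.dual_criterion_edges(mats["HT"], mats["NC"])
        found = {(f.region_i, f.region_j): f.direction for f in findings}
        assert found.get((3, 8)) == "increase"  # region ids are 1-based
        assert found.get((4, 10)) == "decrease"

    def test_null_groups_rarely_yield_findings(self, rng):
        mats = self.sample_groups(rng)
        assert len(en.dual_criterion_edges(mats["HT"], mats["NC"])) <= 1

    def test_invariant_to_subject_order(self, rng):
        mats = self.sample_groups(rng, shift_edges=((2, 7, 0.8),))
        a = en.dual_criterion_edges(mats["HT"], mats["NC"])
        b = en.dual_criterion_edges(mats["HT"][::-1], mats["NC"][::-1])
        assert [dataclasses.asdict(f) for f in a] == [dataclasses.asdict(f) for f in b]

    def test_direction_decomposition(self, rng):
        mats = self.sample_groups(rng, shift_edges=((1, 5, 0.9), (2, 8, -0.9)))
        findings = en.dual_criterion_edges(mats["HT"], mats["NC"])
        n_inc = sum(f.direction == "increase" for f in findings)
        n_dec = sum(f.direction == "decrease" for f in findings)
        assert n_inc + n_dec == len(findings)

    def test_both_scope_is_stricter(self, rng):
        mats = self.sample_groups(rng, shift_edges=((2, 7, 0.8),))
        either = en.dual_criterion_edges(mats["HT"], mats["NC"], criterion1_scope="either")
        both = en.dual_criterion_edges(mats["HT"], mats["NC"], criterion1_scope="both")
        assert len(both) <= len(either)

    def test_recovery_on_default_synthetic_design(self, recovery_design, recovery_matrices):
        findings = en.dual_criterion_edges(
            recovery_matrices["HT"], recovery_matrices["NC"]
        )
        planted = {
            (min(i, j) + 1, max(i, j) + 1): ("decrease" if dz < 0 else "increase")
            for i, j, dz in recovery_design.altered_edges
        }
        hits = {
            (f.region_i, f.region_j)
            for f in findings
            if planted.get((f.region_i, f.region_j)) == f.direction
        }
        assert len(hits) >= 8


class TestAlteredCount:
    @staticmethod
    def finding(i, j, direction):
        return en.EdgeFinding(
            region_i=i, region_j=j, direction=direction,
            t_between=3.0 if direction == "increase" else -3.0,
            p_between=0.001, q_between=0.01,
            within_group_significant={"HT": True, "NC": True},
        )

    def test_subject_at_reference_counts_zero(self, rng):
        R = 6
        nc_mean = rng.normal(0.3, 0.05, (R, R))
        nc_mean = (nc_mean + nc_mean.T) / 2
        nc_sd = np.full((R, R), 0.1)
        findings = [self.finding(1, 4, "increase"), self.finding(2, 5, "decrease")]
        count = en.per_subject_altered_count(zmat(nc_mean), findings, nc_mean, nc_sd)
        assert count.n_alt == 0

    def test_saturated_deviation_counts_all(self, rng):
        R = 6
        nc_mean = np.zeros((R, R))
        nc_sd = np.full((R, R), 0.1)
        z = np.zeros((R, R))
        findings = []
        pairs = [(1, 4, "increase"), (2, 5, "decrease"), (3, 6, "increase")]
        for i, j, d in pairs:
            findings.append(self.finding(i, j, d))
            sign = 1.0 if d == "increase" else -1.0
            z[i - 1, j - 1] = z[j - 1, i - 1] = sign * 1.0  # 10 SD
        count = en.per_subject_altered_count(zmat(z), findings, nc_mean, nc_sd)
        assert count.n_alt == len(findings)

    def test_half_deviating_counts_half(self):
        R = 8
        nc_mean = np.zeros((R, R))
        nc_sd = np.full((R, R), 0.1)
        z = np.zeros((R, R))
        findings = [self.finding(i, i + 4, "increase") for i in (1, 2, 3, 4)]
        for i in (1, 2):  # only two of four edges deviate
            z[i - 1, i + 3] = z[i + 3, i - 1] = 1.0
        count = en.per_subject_altered_count(zmat(z), findings, nc_mean, nc_sd)
        assert count.n_alt == 2

    def test_wrong_direction_not_counted(self):
        R = 4
        nc_mean = np.zeros((R, R))
        nc_sd = np.full((R, R), 0.1)
        z = np.zeros((R, R))
        z[0, 2] = z[2, 0] = -1.0  # deviates downward on an "increase" finding
        count = en.per_subject_altered_count(
            zmat(z), [self.finding(1, 3, "increase")], nc_mean, nc_sd
        )
        assert count.n_alt == 0

    def test_empty_findings_rejected(self, rng):
        with pytest.raises(ValueError):
            en.per_subject_altered_count(
                zmat(np.zeros((3, 3))), [], np.zeros((3, 3)), np.ones((3, 3))
            )
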