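"""DVH, near-maximum, Vx, coverage, Δdose and overlap metrics against
brute-force loop oracles and their ordering invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protonlet as pl
from protonlet import dose_metrics as dm

from conftest import make_grid, random_grid, random_mask
from oracles import (
    d_volume_oracle,
    dvh_volume_oracle,
    mean_oracle,
    overlap_oracle,
    percentile_exceeded_by,
    v_dose_oracle,
    volume_above_oracle,
)


def full_mask(shape, spacing=(2.0, 2.0, 2.0), name="all"):
    return pl.StructureMask(name, np.ones(shape, bool), spacing)


class TestDVH:
    def test_uniform_structure_is_step_function(self):
        grid = make_grid(np.full((4, 4, 4), 10.0))
        curve = dm.dvh(grid, full_mask((4, 4, 4)), n_bins=50, dose_max=20.0)
        assert curve.volume_at(0.0) == 100.0
        assert curve.volume_at(9.9) == pytest.approx(100.0, abs=1.0)
        assert curve.volume_at(10.5) == pytest.approx(0.0, abs=1.0)

    def test_half_half_v5(self):
        vals = np.concatenate([np.full(32, 4.0), np.full(32, 8.0)]).reshape(4, 4, 4)
        curve = dm.dvh(make_grid(vals), full_mask((4, 4, 4)), dose_max=10.0)
        assert curve.volume_at(5.0) == pytest.approx(50.0)

    def test_bin_edges_match_counting_oracle(self, rng):
        grid = random_grid(rng, shape=(5, 5, 5))
        mask = full_mask((5, 5, 5))
        curve = dm.dvh(grid, mask, n_bins=20)
        vals = grid.values.ravel()
        for edge, vol in zip(curve.dose_axis, curve.volume_axis):
            assert vol == pytest.approx(dvh_volume_oracle(vals, edge), rel=1e-9)

    def test_non_increasing(self, rng):
        curve = dm.dvh(random_grid(rng), random_mask(rng))
        assert np.all(np.diff(curve.volume_axis) <= 0)

    def test_excluded_voxels_omitted(self):
        vals = np.full((3, 1, 1), 6.0)
        vals[0, 0, 0] = pl.SENTINEL
        curve = dm.dvh(make_grid(vals, quantity="let_keVum"), full_mask((3, 1, 1)),
                       dose_max=10.0)
        assert curve.volume_at(5.0) == pytest.approx(100.0)  # 2 of 2 evaluable

    def test_empty_mask_signals_too_small(self, rng):
        empty = pl.StructureMask("none", np.zeros((3, 3, 3), bool), (2, 2, 2))
        with pytest.raises(dm.StructureTooSmallError):
            dm.dvh(random_grid(rng, shape=(3, 3, 3)), empty)


class TestDVolume:
    def test_two_hottest_voxels_span_exactly(self):
        # voxel volume 0.05 cc -> spacing (5, 5, 2) mm; doses 10, 9, 8, ...
        vals = np.array([10.0, 9.0, 8.0, 7.0]).reshape(4, 1, 1)
        grid = pl.VoxelGrid(vals, (5.0, 5.0, 2.0))
        mask = full_mask((4, 1, 1), spacing=(5.0, 5.0, 2.0))
        assert mask.voxel_volume_cc == pytest.approx(0.05)
        assert dm.d_volume(grid, mask, 0.1) == pytest.approx(9.0)

    def test_full_volume_is_minimum(self, rng):
        grid = random_grid(rng, shape=(4, 4, 4))
        mask = full_mask((4, 4, 4))
        assert dm.d_volume(grid, mask, mask.volume_cc) == pytest.approx(grid.values.min())

    def test_matches_cumulative_sort_oracle(self, rng):
        mask = random_mask(rng, shape=(8, 8, 8), p=0.5)
        grid = random_grid(rng, shape=(8, 8, 8))
        for v in (0.1, 0.5, 1.0):
            ref = d_volume_oracle(grid.values[mask.mask], mask.voxel_volume_cc, v)
            assert dm.d_volume(grid, mask, v) == pytest.approx(ref, rel=1e-9)

    def test_structure_too_small(self):
        grid = make_grid(np.ones((2, 1, 1)))
        mask = full_mask((2, 1, 1))  # 0.016 cc
        with pytest.raises(dm.StructureTooSmallError):
            dm.d_volume(grid, mask, 0.1)

    @given(st.integers(0, 5000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_non_increasing_in_volume(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_grid(rng, shape=(6, 6, 6))
        mask = full_mask((6, 6, 6))
        vols = np.linspace(0.05, mask.volume_cc, 15)
        vals = [dm.d_volume(grid, mask, v) for v in vols]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_quantized_mode(self, rng):
        grid = random_grid(rng, shape=(5, 5, 5))
        mask = full_mask((5, 5, 5))
        vq = dm.d_volume(grid, mask, 0.1, interpolate=False)
        assert vq in grid.values  # an actual voxel value


class TestSimpleStatistics:
    def test_mean_uniform_and_oracle(self, rng):
        grid = make_grid(np.full((3, 3, 3), 4.5))
        assert dm.mean_in_mask(grid, full_mask((3, 3, 3))) == pytest.approx(4.5)
        g = random_grid(rng)
        m = random_mask(rng)
        assert dm.mean_in_mask(g, m) == pytest.approx(
            mean_oracle(g.values[m.mask]), rel=1e-12)

    def test_mean_empty_mask_errors(self, rng):
        empty = pl.StructureMask("none", np.zeros((3, 3, 3), bool), (2, 2, 2))
        with pytest.raises(dm.StructureTooSmallError):
            dm.mean_in_mask(random_grid(rng, shape=(3, 3, 3)), empty)

    def test_v_dose_limits_and_half(self, rng):
        g = random_grid(rng)
        m = full_mask(g.shape)
        assert dm.v_dose(g, m, 0.0) == 100.0
        assert dm.v_dose(g, m, g.values.max() + 1) == 0.0
        vals = np.concatenate([np.full(50, 4.0), np.full(50, 8.0)]).reshape(10, 10, 1)
        assert dm.v_dose(make_grid(vals), full_mask((10, 10, 1)), 5.0) == 50.0

    def test_v_dose_oracle(self, rng):
        g = random_grid(rng)
        m = random_mask(rng)
        assert dm.v_dose(g, m, 10.0) == pytest.approx(
            v_dose_oracle(g.values[m.mask], 10.0), rel=1e-12)

    def test_ordering_dmean_d01cc_dmax(self, rng):
        for _ in range(20):
            g = random_grid(rng, shape=(8, 8, 8))
            m = random_mask(rng, shape=(8, 8, 8), p=0.6)
            if m.volume_cc < 0.1:
                continue
            dmean = dm.mean_in_mask(g, m)
            d01 = dm.d_volume(g, m, 0.1)
            dmax = g.values[m.mask].max()
            assert dmean <= d01 + 1e-12 <= dmax + 1e-12

    def test_dvh_vx_agrees_with_v_dose_within_bin(self, rng):
        g = random_grid(rng)
        m = random_mask(rng, p=0.7)
        curve = dm.dvh(g, m, n_bins=400, dose_max=25.0)
        for thr in (5.0, 10.0):
            assert curve.volume_at(thr) == pytest.approx(
                dm.v_dose(g, m, thr), abs=100.0 / m.n_voxels + 1.0)


class TestCoverage:
    def test_uniform_pass_and_fail(self):
        m = full_mask((5, 5, 5))
        ok = dm.coverage_check(make_grid(np.full((5, 5, 5), 19.8)), m, 19.8)
        assert ok["pass"] and ok["d98"] == pytest.approx(19.8)
        bad = dm.coverage_check(make_grid(np.full((5, 5, 5), 0.9 * 19.8)), m, 19.8)
        assert not bad["pass"]

    def test_graded_ctv_against_percentile_oracle(self, rng):
        vals = 19.8 * (0.9 + 0.2 * rng.random((10, 10, 10)))
        grid = make_grid(vals)
        m = full_mask((10, 10, 10))
        res = dm.coverage_check(grid, m, 19.8)
        ref = percentile_exceeded_by(vals.ravel().tolist(), 0.98)
        assert res["d98"] == pytest.approx(ref, rel=2e-3)


class TestDeltaAndOverlap:
    def test_identical_inputs_zero_map(self, rng):
        g = random_grid(rng, quantity="dose_Gy_rbe")
        delta = dm.delta_dose_map(g, g)
        assert np.all(delta.values == 0)

    def test_excluded_propagates(self, rng):
        g = random_grid(rng, shape=(3, 3, 3), quantity="dose_Gy_rbe")
        incl = np.ones((3, 3, 3), bool)
        incl[1, 1, 1] = False
        delta = dm.delta_dose_map(g, g, incl)
        assert np.isnan(delta.values[1, 1, 1])
        assert np.isfinite(delta.values).sum() == 26

    def test_volume_above_examples_and_oracle(self, rng):
        below = make_grid(np.full((4, 4, 4), 1.0), quantity="delta_Gy_rbe")
        assert dm.volume_above(below, 3.0) == 0.0
        vals = np.zeros((4, 4, 4))
        vals[:2, 0, 0] = 5.0
        g = make_grid(vals, quantity="delta_Gy_rbe")
        assert dm.volume_above(g, 3.0) == pytest.approx(2 * g.voxel_volume_cc)
        r = random_grid(rng, quantity="delta_Gy_rbe")
        assert dm.volume_above(r, 12.0) == pytest.approx(
            volume_above_oracle(r.values.ravel(), r.voxel_volume_cc, 12.0), rel=1e-12)

    def test_volume_above_with_mask(self, rng):
        r = random_grid(rng, quantity="delta_Gy_rbe")
        m = random_mask(rng)
        ref = volume_above_oracle(r.values[m.mask], m.voxel_volume_cc, 10.0)
        assert dm.volume_above(r, 10.0, m) == pytest.approx(ref, rel=1e-12)

    def test_overlap_disjoint_is_zero(self):
        dose = np.zeros((4, 1, 1))
        dose[0] = 10.0
        let = np.zeros((4, 1, 1))
        let[3] = 9.0
        res = dm.overlap_volume(make_grid(dose), make_grid(let, quantity="let_keVum"))
        assert res["volume_cc"] == 0.0

    def test_constructed_three_voxel_overlap(self):
        # voxel volume 0.008 cc (2 mm isotropic); 3 qualifying voxels -> 0.024 cc
        dose = np.full((3, 1, 1), 10.0)
        let = np.full((3, 1, 1), 7.0)
        res = dm.overlap_volume(make_grid(dose), make_grid(let, quantity="let_keVum"),
                                0.8, 6.0)
        assert res["volume_cc"] == pytest.approx(0.024)

    def test_overlap_matches_boolean_oracle(self, rng):
        dose = random_grid(rng)
        let = random_grid(rng, scale=12.0, quantity="let_keVum")
        res = dm.overlap_volume(dose, let, 0.8, 6.0)
        ref = overlap_oracle(dose.values.ravel(), let.values.ravel(),
                             dose.voxel_volume_cc, 0.8 * dose.values.max(), 6.0)
        assert res["volume_cc"] == pytest.approx(ref, rel=1e-12)

    def test_overlap_reports_component_structures(self, rng):
        dose = make_grid(np.full((4, 4, 4), 10.0))
        let = make_grid(np.full((4, 4, 4), 8.0), quantity="let_keVum")
        hit = random_mask(rng, shape=(4, 4, 4), p=0.5, name="hit")
        miss = pl.StructureMask("miss", np.zeros((4, 4, 4), bool), (2, 2, 2))
        res = dm.overlap_volume(dose, let, structures={"hit": hit, "miss": miss})
        assert res["component_structures"] == ["hit"]

    def test_volume_cc_is_exact_count_times_voxel(self, rng):
        m = random_mask(rng, spacing=(2.5, 2.0, 3.0))
        assert m.volume_cc == m.n_voxels * (2.5 * 2.0 * 3.0) / 1000.0
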