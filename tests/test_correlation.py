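"""Spearman statistic, GTV sampling, regional partitioning, cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from petmrcorr.correlation import (InsufficientSamplesError, MIN_REGIONS,
                                   RegionSpec, UndefinedCorrelationError,
                                   block_extent_mm, cohort_summary,
                                   partition_regions,
                                   patient_correlation_matrix,
                                   regional_samples, spearman, voxel_samples)
from petmrcorr.grids_io import ImageGrid, ParametricMap, ROIMask

PET_SPACING = (2.8, 2.8, 2.0)


def brute_force_spearman(x, y):
    """Independent oracle: explicit average ranks + the Pearson formula."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
            i = j
        return r
    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    n = len(rx)
    sxy = np.sum(rx * ry) - n * rx.mean() * ry.mean()
    sxx = np.sum(rx * rx) - n * rx.mean() ** 2
    syy = np.sum(ry * ry) - n * ry.mean() ** 2
    return sxy / np.sqrt(sxx * syy)


class TestSpearman:
    def test_comonotone_identity(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_hand_example_permutation(self):
        assert spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5, abs=1e-12)

    def test_hand_example_with_ties(self):
        # ranks (1.5, 1.5, 3) vs (1, 2, 3): r = 1.5 / sqrt(3)
        assert spearman([1, 1, 2], [1, 2, 3]) == pytest.approx(
            1.5 / np.sqrt(3.0), abs=1e-12)

    def test_monotone_invariance_exponential(self):
        x = np.array([0.3, -1.2, 2.0, 0.7, -0.1])
        assert spearman(x, np.exp(x)) == 1.0

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(202)
        worst = 0.0
        for _ in range(1000):
            n = rng.integers(5, 40)
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n) + rng.normal(0, 0.5, n)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            worst = max(worst, abs(spearman(x, y) - brute_force_spearman(x, y)))
        assert worst < 1e-12

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.integers(0, 8, 20).astype(float)
            y = rng.normal(size=20)
            if np.all(x == x[0]):
                continue
            ref = stats.spearmanr(x, y).statistic
            assert spearman(x, y) == pytest.approx(ref, abs=1e-12)

    @given(st.lists(st.integers(-100, 100), min_size=4, max_size=30, unique=True),
           st.floats(0.1, 5.0), st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_invariance_property(self, xs, a, b):
        x = np.array(xs, dtype=float)
        rng = np.random.default_rng(int(abs(x[0] * 1000)) % 2 ** 31)
        y = rng.permutation(x)
        r = spearman(x, y)
        assert spearman(a * x + 1.0, np.exp(b * (y / 100.0))) == pytest.approx(
            r, abs=1e-12)

    def test_antisymmetry_without_ties(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert spearman(x, -y) == pytest.approx(-spearman(x, y), abs=1e-12)


class TestVoxelSamples:
    def _setup(self):
        g = ImageGrid((10, 10, 1), PET_SPACING)
        gtv = np.zeros(g.shape, bool)
        gtv.ravel()[:100] = True  # all voxels
        rng = np.random.default_rng(3)
        a = ParametricMap(g, rng.random(g.shape), "SUV", "A")
        b = ParametricMap(g, rng.random(g.shape), "TBR", "B")
        return g, ROIMask(g, gtv, "GTV"), a, b

    def test_counts_all_valid_voxels(self):
        _, gtv, a, b = self._setup()
        ss = voxel_samples(a, b, gtv)
        assert ss.n == 100 and ss.n_dropped == 0

    def test_invalid_voxels_dropped_and_reported(self):
        _, gtv, a, b = self._setup()
        vals = a.values.copy()
        vals.ravel()[:10] = np.nan
        ss = voxel_samples(a.with_values(vals), b, gtv)
        assert ss.n == 90 and ss.n_dropped == 10

    def test_too_few_samples_raises(self):
        g, _, a, b = self._setup()
        m = np.zeros(g.shape, bool)
        m[0, 0, 0] = True
        with pytest.raises(InsufficientSamplesError):
            voxel_samples(a, b, ROIMask(g, m, "GTV"))


class TestPartitionRegions:
    def _mask(self, shape_on, grid_shape=(20, 20, 20)):
        g = ImageGrid(grid_shape, PET_SPACING)
        m = np.zeros(g.shape, bool)
        m[2:2 + shape_on[0], 3:3 + shape_on[1], 4:4 + shape_on[2]] = True
        return ROIMask(g, m, "GTV")

    def test_single_aligned_block(self):
        regions = partition_regions(self._mask((3, 3, 4)))
        assert len(regions) == 1
        assert regions[0].shape == (36, 3)

    def test_aligned_box_tiles_to_eight(self):
        regions = partition_regions(self._mask((6, 6, 8)))
        assert len(regions) == 8
        assert all(r.shape[0] == 36 for r in regions)

    def test_block_physical_extent_on_pet_grid(self):
        g = ImageGrid((10, 10, 10), (2.8, 2.8, 2.0))
        assert block_extent_mm(RegionSpec(), g) == pytest.approx((8.4, 8.4, 8.0))

    def test_partial_blocks_follow_occupancy_rule(self):
        # 4x3x4 box: one full block plus a 1-voxel-thick sliver (12/36 < 0.5)
        regions = partition_regions(self._mask((4, 3, 4)))
        assert len(regions) == 1
        regions = partition_regions(self._mask((4, 3, 4)),
                                    RegionSpec(min_gtv_fraction=0.3))
        assert len(regions) == 2
        assert {r.shape[0] for r in regions} == {36, 12}

    def test_empty_result_when_gtv_below_occupancy(self):
        regions = partition_regions(self._mask((2, 2, 2)))
        assert regions == []


class TestRegionalSamples:
    def _grid(self):
        return ImageGrid((6, 6, 8), PET_SPACING)

    def test_constant_maps_give_constant_samples(self):
        g = self._grid()
        gtv = ROIMask(g, np.ones(g.shape, bool), "GTV")
        regions = partition_regions(gtv)
        a = ParametricMap(g, np.full(g.shape, 2.5), "SUV", "A")
        b = ParametricMap(g, np.full(g.shape, 7.0), "TBR", "B")
        ss = regional_samples(a, b, regions)
        assert np.allclose(ss.x, 2.5) and np.allclose(ss.y, 7.0)

    def test_mean_of_one_to_thirtysix(self):
        g = ImageGrid((3, 3, 8), PET_SPACING)
        gtv = ROIMask(g, np.ones(g.shape, bool), "GTV")
        regions = partition_regions(gtv)
        assert len(regions) == 2
        vals = np.zeros(g.shape)
        first = regions[0]
        vals[first[:, 0], first[:, 1], first[:, 2]] = np.arange(1.0, 37.0)
        a = ParametricMap(g, vals, "SUV", "A")
        ss = regional_samples(a, a.with_values(2 * vals), regions)
        assert ss.x[0] == pytest.approx(18.5)  # mean of 1..36

    def test_block_constant_maps_match_voxel_per_block(self, rng):
        g = self._grid()
        gtv = ROIMask(g, np.ones(g.shape, bool), "GTV")
        regions = partition_regions(gtv)
        va = np.zeros(g.shape)
        vb = np.zeros(g.shape)
        for r in regions:
            va[r[:, 0], r[:, 1], r[:, 2]] = rng.random()
            vb[r[:, 0], r[:, 1], r[:, 2]] = rng.random()
        a = ParametricMap(g, va, "SUV", "A")
        b = ParametricMap(g, vb, "TBR", "B")
        ss = regional_samples(a, b, regions)
        one_per_block = np.array([[va[tuple(r[0])], vb[tuple(r[0])]]
                                  for r in regions])
        assert spearman(ss.x, ss.y) == pytest.approx(
            spearman(one_per_block[:, 0], one_per_block[:, 1]), abs=1e-12)


class TestPatientMatrixAndCohort:
    def _patient_maps(self, g, rng, labels=("FDG", "FMISO")):
        return {lab: ParametricMap(g, rng.random(g.shape), "au", lab)
                for lab in labels}

    def test_identical_maps_correlate_perfectly(self, rng):
        g = ImageGrid((6, 6, 8), PET_SPACING)
        gtv = ROIMask(g, np.ones(g.shape, bool), "GTV")
        m = ParametricMap(g, rng.random(g.shape), "au", "A")
        res = patient_correlation_matrix({"A": m, "B": m.with_values(m.values,
                                                                     name="B")},
                                         gtv, level="voxel")
        assert res.r("A", "B") == 1.0

    def test_nine_subregions_excluded_from_regional(self, rng):
        g = ImageGrid((12, 12, 6), PET_SPACING)
        m = np.zeros(g.shape, bool)
        m[1:10, 1:10, 1:5] = True  # 9x9x4 voxels -> 3x3x1 = 9 aligned blocks
        gtv = ROIMask(g, m, "GTV")
        assert len(partition_regions(gtv)) == 9
        maps = self._patient_maps(g, rng)
        reg = patient_correlation_matrix(maps, gtv, level="regional",
                                         patient_id="p9")
        vox = patient_correlation_matrix(maps, gtv, level="voxel",
                                         patient_id="p9")
        assert reg.excluded and reg.n_regions == 9 and not reg.pairs
        assert not vox.excluded and vox.pairs
        summary = cohort_summary([vox, reg])
        assert set(summary.level) == {"voxel"}

    def test_missing_modalities_yield_absent_pairs(self, rng):
        g = ImageGrid((6, 6, 8), PET_SPACING)
        gtv = ROIMask(g, np.ones(g.shape, bool), "GTV")
        maps = self._patient_maps(g, rng, labels=("FDG", "FMISO", "ADC"))
        maps["dS_DCE"] = None  # patient without DCE-MRI
        res = patient_correlation_matrix(maps, gtv, level="voxel")
        assert ("FDG", "dS_DCE") not in res.pairs
        assert len(res.pairs) == 3  # all pairs among the three present maps

    def test_cohort_summary_order_statistics(self):
        from petmrcorr.correlation import CorrelationResult
        results = []
        for pid, r in zip("abc", (0.2, 0.5, 0.9)):
            res = CorrelationResult(pid, "voxel", ["A", "B"])
            res.pairs[("A", "B")] = (r, 100)
            results.append(res)
        s = cohort_summary(results)
        row = s.iloc[0]
        assert row["median_r"] == 0.5
        assert (row["min_r"], row["max_r"]) == (0.2, 0.9)
        assert row["n_patients"] == 3

    def test_single_patient_degenerate_range(self):
        from petmrcorr.correlation import CorrelationResult
        res = CorrelationResult("solo", "voxel", ["A", "B"])
        res.pairs[("A", "B")] = (0.42, 50)
        s = cohort_summary([res])
        assert s.iloc[0]["median_r"] == 0.42
        assert s.iloc[0]["min_r"] == s.iloc[0]["max_r"] == 0.42
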