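import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hpmfm import (
    DiscretizationConfig,
    ParametricMapSet,
    cohort_feature_matrix,
    discretize,
    extract_patient_features,
    first_order_features,
    shape_elongation,
    total_metabolic_volume,
)


class TestDiscretize:
    def test_floor_rule_by_hand(self):
        levels, n = discretize(np.array([0.0, 0.0005, 0.0012]), 0.001)
        assert list(levels) == [1, 1, 2]
        assert n == 2

    def test_constant_roi_single_level(self):
        levels, n = discretize(np.full(10, 3.3), 0.5)
        assert n == 1 and set(levels) == {1}

    def test_range_of_exactly_43_widths_gives_43_bins(self):
        """Matches the k_PL map's bin count when the range spans 43 widths."""
        w = 0.001
        vals = np.concatenate([[0.0, 43 * w], np.linspace(0, 43 * w, 37)])
        levels, n = discretize(vals, w)
        assert n == 43
        assert levels.max() == 43 and levels.min() == 1

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.array([]), 0.1)


class TestFirstOrder:
    def test_simple_examples(self):
        f = first_order_features(np.array([1.0, 2, 3, 4]), width=1.0)
        assert f["Mean"] == 2.5 and f["Median"] == 2.5 and f["Range"] == 3.0
        assert f["Minimum"] == 1.0 and f["Maximum"] == 4.0
        assert f["Energy"] == pytest.approx(30.0)

    def test_constant_roi_degenerate_values(self):
        f = first_order_features(np.full(20, 7.0), width=0.5)
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Kurtosis"] == 1.0  # lower bound convention for constants

    def test_normal_sample_kurtosis_near_3(self):
        rng = np.random.default_rng(31)
        v = rng.normal(size=100_000)
        f = first_order_features(v, width=0.1)
        assert f["Kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_feature_count_is_18(self):
        f = first_order_features(np.array([1.0, 2, 3, 4]), width=1.0)
        assert len(f) == 18

    # values on a 0.25 grid (exact binary fractions) so a shift can never
    # move a value across a bin edge through rounding alone
    @given(
        st.lists(st.integers(-200, 200).map(lambda k: k * 0.25),
                 min_size=5, max_size=40),
        st.integers(1, 40).map(lambda k: k * 0.25),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_moves_location_not_dispersion(self, vals, c):
        """x -> x + c shifts location features by c, leaves the rest."""
        v = np.asarray(vals)
        a = first_order_features(v, width=0.5)
        b = first_order_features(v + c, width=0.5)
        for name in ("Mean", "Median", "10Percentile", "90Percentile"):
            assert b[name] == pytest.approx(a[name] + c, rel=1e-9, abs=1e-9)
        for name in ("Variance", "Entropy", "Uniformity", "Range",
                     "InterquartileRange", "MeanAbsoluteDeviation"):
            assert b[name] == pytest.approx(a[name], rel=1e-9, abs=1e-9)

    @given(st.lists(st.floats(-100, 100).map(lambda v: round(v, 3)),
                    min_size=2, max_size=50))
    @settings(max_examples=80, deadline=None)
    def test_kurtosis_pearson_bound(self, vals):
        v = np.asarray(vals)
        f = first_order_features(v, width=1.0)
        assert f["Kurtosis"] >= 1.0 - 1e-9

    def test_order_invariance(self, rng):
        v = rng.uniform(0, 5, 60)
        a = first_order_features(v, width=0.3)
        b = first_order_features(v[::-1].copy(), width=0.3)
        for name in a:  # summation order may differ at float precision
            assert b[name] == pytest.approx(a[name], rel=1e-12), name


class TestShapeElongation:
    def test_cube_is_isotropic(self):
        coords = np.argwhere(np.ones((4, 4, 4))).astype(float)
        assert shape_elongation(coords) == pytest.approx(1.0)

    def test_collinear_is_zero(self):
        coords = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        assert shape_elongation(coords) == pytest.approx(0.0, abs=1e-12)

    def test_ellipsoid_axis_ratio(self):
        """Semi-axes 20:10:10 mm -> sqrt(lambda2/lambda1) ~ 0.5."""
        grid = np.indices((42, 22, 22)).reshape(3, -1).T * 2.0  # 2 mm voxels
        center = np.array([40.0, 20.0, 20.0])
        d = (grid - center) / np.array([20.0, 10.0, 10.0])
        coords = grid[(d ** 2).sum(axis=1) <= 1.0]
        assert shape_elongation(coords) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_roi_is_nan(self):
        assert np.isnan(shape_elongation(np.zeros((1, 3))))
        assert np.isnan(shape_elongation(np.ones((5, 3))))


def _synthetic_maps(kpl_values_by_label, voxel=5.0):
    """Cuboid lesions side by side with prescribed k_PL values."""
    shape = (10, 6, 6)
    aff = np.diag([voxel, voxel, voxel, 1.0])
    kpl = np.zeros(shape)
    mask = np.zeros(shape, np.int16)
    x0 = 0
    for lab, (val, nx) in kpl_values_by_label.items():
        mask[x0 : x0 + nx, 1:4, 1:4] = lab
        kpl[x0 : x0 + nx, 1:4, 1:4] = val
        x0 += nx + 1
    return ParametricMapSet(kpl, kpl * 0.1 + 1.0, kpl * 0.0 + 25.0, mask, aff)


class TestTmvAndAggregation:
    def test_tmv_simple_count(self):
        maps = _synthetic_maps({1: (17.0, 1)})  # 1x3x3 block = 9 voxels
        assert total_metabolic_volume(maps) == pytest.approx(9 * 0.125)

    def test_tmv_empty_mask(self):
        maps = _synthetic_maps({1: (17.0, 1)})
        maps.mask[:] = 0
        assert total_metabolic_volume(maps) == 0.0

    def test_uniform_lesion_median(self):
        maps = _synthetic_maps({1: (17.0, 2)})
        f = extract_patient_features(maps)
        assert f["kPL_original_firstorder_Median"] == pytest.approx(17.0)

    def test_merged_median_pools_equal_volumes(self):
        """Two equal lesions at 10 and 30 ks^-1 pool to median 20."""
        maps = _synthetic_maps({1: (10.0, 2), 2: (30.0, 2)})
        f = extract_patient_features(maps, mode="merged")
        assert f["kPL_original_firstorder_Median"] == pytest.approx(20.0)

    def test_per_lesion_mode_weighted_average(self):
        maps = _synthetic_maps({1: (10.0, 2), 2: (30.0, 2)})
        f = extract_patient_features(maps, mode="per_lesion")
        assert f["kPL_original_firstorder_Median"] == pytest.approx(20.0)
        assert f["TMV"] == pytest.approx(total_metabolic_volume(maps))

    def test_no_lesion_rejected(self):
        maps = _synthetic_maps({1: (17.0, 1)})
        maps.mask[:] = 0
        with pytest.raises(ValueError, match="no lesions"):
            extract_patient_features(maps)


class TestCohortMatrix:
    def test_schema_stable_across_patients(self, small_cohort):
        from hpmfm import DynamicSeries, compute_maps, resample_maps

        maps = {}
        for pt in small_cohort.patients[:3]:
            native = compute_maps(DynamicSeries.from_patient(pt), pt.mask)
            maps[pt.patient_id] = resample_maps(native)
        df = cohort_feature_matrix(maps)
        assert df.shape[0] == 3
        assert df.notna().all().all()
        assert df.shape[1] == 196  # 3 maps x (18 + 1 + 46) + TMV
        assert "kPL_original_firstorder_90Percentile" in df.columns
        assert "pyrAUC_original_shape_Elongation" in df.columns

    def test_texture_shift_invariance_through_extraction(self):
        """Adding a constant to a map leaves its texture features alone."""
        maps = _synthetic_maps({1: (10.0, 3)})
        rng = np.random.default_rng(4)
        maps.kpl_map[maps.mask > 0] += rng.uniform(0, 5, (maps.mask > 0).sum())
        f1 = extract_patient_features(maps)
        maps2 = ParametricMapSet(
            maps.kpl_map + 11.0, maps.pyr_auc_map, maps.mean_time_map,
            maps.mask, maps.affine,
        )
        f2 = extract_patient_features(maps2)
        for name in f1:
            if "_glrlm_" in name or "_glszm_" in name or "_gldm_" in name:
                assert f2[name] == pytest.approx(f1[name], rel=1e-9), name
        assert f2["kPL_original_firstorder_Median"] == pytest.approx(
            f1["kPL_original_firstorder_Median"] + 11.0
        )
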