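import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spectcv as sc
from spectcv.cvmap import CVMatrix, mean_frequency_function
from spectcv.errors import AnalysisError, SettingsError


def _cvm_from_values(values):
    """CV matrix holding the given values at synthetic valid centres."""
    values = np.asarray(values, dtype=float)
    grid = np.full((values.size, 1, 1), np.nan)
    grid[:, 0, 0] = values
    valid = ~np.isnan(grid)
    return CVMatrix(grid, valid, sc.CVSettings(), 3.3)


class TestKernelGeometry:
    @pytest.mark.parametrize(
        "pitch,expected_side",
        [(3.3, 9), (3.45, 9), (1.65, 19), (6.6, 5), (10.0, 3)],
    )
    def test_kernel_side_rounds_to_odd(self, pitch, expected_side):
        assert sc.CVSettings().kernel_voxels(pitch) == expected_side

    def test_clinical_kernel_holds_729_voxels(self):
        assert sc.CVSettings().kernel_voxels(3.3) ** 3 == 729

    def test_kernel_larger_than_grid_rejected(self):
        vol = sc.ActivityVolume(np.ones((4, 4, 4)), 3.3)
        mask = sc.LungMask(np.ones((4, 4, 4), bool), 3.3)
        with pytest.raises(SettingsError):
            sc.cv_kernel(vol, mask)  # 9-voxel kernel on a 4-voxel grid


class TestCvKernel:
    def test_constant_volume_gives_zero_cv(self, small_mask):
        vol = sc.ActivityVolume(
            np.full(small_mask.shape, 3.0), small_mask.voxel_pitch_mm
        )
        cvm = sc.cv_kernel(vol, small_mask)
        assert cvm.n_valid > 0
        assert np.allclose(cvm.cv_values, 0.0, atol=1e-4)

    def test_hand_computed_example(self):
        # kernel covering exactly the in-mask values {1, 2, 3}:
        # mean 2, sample SD 1 -> CV 50%
        vol = np.zeros((5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        vol[2, 2, 1:4] = [1.0, 2.0, 3.0]
        mask[2, 2, 1:4] = True
        settings = sc.CVSettings(kernel_side_cm=3.0)  # 3 voxels at 10 mm pitch
        cvm = sc.cv_kernel(sc.ActivityVolume(vol, 10.0), sc.LungMask(mask, 10.0), settings)
        assert cvm.values[2, 2, 2] == pytest.approx(50.0)

    def test_poisson_field_cv_is_inverse_sqrt_mean(self):
        rng = np.random.default_rng(11)
        vol = rng.poisson(100.0, size=(31, 31, 31)).astype(float)
        mask = np.ones_like(vol, bool)
        cvm = sc.cv_kernel(sc.ActivityVolume(vol, 3.3), sc.LungMask(mask, 3.3))
        interior = cvm.values[10:21, 10:21, 10:21]
        assert interior.mean() == pytest.approx(10.0, abs=1.0)

    def test_scale_invariance(self, small_mask):
        rng = np.random.default_rng(4)
        data = rng.uniform(0.5, 2.0, small_mask.shape)
        a = sc.cv_kernel(
            sc.ActivityVolume(data, small_mask.voxel_pitch_mm), small_mask
        )
        b = sc.cv_kernel(
            sc.ActivityVolume(data * 37.5, small_mask.voxel_pitch_mm), small_mask
        )
        assert np.allclose(a.values[a.valid], b.values[b.valid], rtol=1e-9)

    def test_out_of_mask_voxels_excluded(self):
        # a hot voxel just outside the mask must not influence any kernel
        vol = np.ones((9, 9, 9))
        mask = np.zeros((9, 9, 9), bool)
        mask[3:6, 3:6, 3:6] = True
        vol[0, 0, 0] = 1e6
        settings = sc.CVSettings(kernel_side_cm=3.0)
        cvm = sc.cv_kernel(sc.ActivityVolume(vol, 10.0), sc.LungMask(mask, 10.0), settings)
        assert np.allclose(cvm.cv_values, 0.0, atol=1e-9)

    def test_min_kernel_voxels_enforced(self):
        vol = np.ones((9, 9, 9))
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True  # a single isolated voxel: SD undefined
        settings = sc.CVSettings(kernel_side_cm=3.0)
        cvm = sc.cv_kernel(sc.ActivityVolume(vol, 10.0), sc.LungMask(mask, 10.0), settings)
        assert cvm.n_valid == 0


class TestFrequencyFunction:
    def test_direct_counting(self):
        ff = sc.frequency_function(_cvm_from_values([0.5, 1.5, 1.7]))
        assert ff.frequencies_percent[0] == pytest.approx(100 / 3)
        assert ff.frequencies_percent[1] == pytest.approx(200 / 3)
        assert ff.bin_left[0] == 0.0

    def test_identical_values_single_bin(self):
        ff = sc.frequency_function(_cvm_from_values([12.3] * 5))
        assert ff.frequencies_percent.max() == pytest.approx(100.0)
        assert ff.bin_left[np.argmax(ff.frequencies_percent)] == 12.0

    @given(
        st.lists(st.floats(0, 80, allow_nan=False), min_size=1, max_size=200)
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_area_is_100_percent(self, values):
        ff = sc.frequency_function(_cvm_from_values(values))
        assert ff.frequencies_percent.sum() == pytest.approx(100.0, abs=1e-9)
        assert (ff.frequencies_percent >= 0).all()

    def test_empty_matrix_rejected(self):
        empty = CVMatrix(
            np.full((2, 2, 2), np.nan), np.zeros((2, 2, 2), bool), sc.CVSettings(), 3.3
        )
        with pytest.raises(AnalysisError):
            sc.frequency_function(empty)


class TestModalCvt:
    def test_unique_peak_midpoint(self):
        ff = sc.frequency_function(_cvm_from_values([20.2, 20.7, 20.4, 5.0]))
        assert sc.modal_cvt([ff]) == pytest.approx(20.5)

    def test_tie_breaks_to_lower_bin(self):
        ff = sc.frequency_function(_cvm_from_values([5.5, 9.5]))
        assert sc.modal_cvt([ff]) == pytest.approx(5.5)

    def test_mean_over_group(self):
        # group mean peaks where the pooled mass is largest
        f1 = sc.frequency_function(_cvm_from_values([10.5, 10.6, 20.5]))
        f2 = sc.frequency_function(_cvm_from_values([20.1, 20.2, 10.1]))
        f3 = sc.frequency_function(_cvm_from_values([20.3, 20.8, 20.4]))
        assert sc.modal_cvt([f1, f2, f3]) == pytest.approx(20.5)
        mean_ff = mean_frequency_function([f1, f2, f3])
        assert mean_ff.frequencies_percent.sum() == pytest.approx(100.0)

    def test_inconsistent_binning_rejected(self):
        from spectcv.cvmap import FrequencyFunction

        a = FrequencyFunction(np.array([0.0, 1.0]), np.array([50.0, 50.0]), 1.0)
        b = FrequencyFunction(np.array([0.0, 2.0]), np.array([50.0, 50.0]), 2.0)
        with pytest.raises(SettingsError):
            sc.modal_cvt([a, b])


class TestAucAbove:
    def test_endpoints(self):
        cvm = _cvm_from_values([5.0, 10.0, 15.0])
        assert sc.auc_above(cvm, 0.0) == 100.0
        assert sc.auc_above(cvm, 99.0) == 0.0

    def test_strictly_greater(self):
        cvm = _cvm_from_values([5.0, 10.0, 15.0])
        assert sc.auc_above(cvm, 10.0) == pytest.approx(100 / 3)

    def test_uniform_distribution_half_mass(self):
        rng = np.random.default_rng(2)
        cvm = _cvm_from_values(rng.uniform(0, 10, 4000))
        assert sc.auc_above(cvm, 5.0) == pytest.approx(50.0, abs=2.5)

    @given(st.lists(st.floats(0, 60, allow_nan=False), min_size=2, max_size=100))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_non_increasing_in_threshold(self, values):
        cvm = _cvm_from_values(values)
        aucs = [sc.auc_above(cvm, t) for t in (0.0, 5.0, 20.0, 45.0)]
        assert all(a >= b for a, b in zip(aucs, aucs[1:]))

    def test_matches_binned_tail_within_one_bin(self):
        rng = np.random.default_rng(8)
        values = rng.normal(20, 4, 5000).clip(0)
        cvm = _cvm_from_values(values)
        ff = sc.frequency_function(cvm)
        cvt = 17.5
        binned_tail = ff.frequencies_percent[ff.bin_left >= np.floor(cvt)].sum()
        raw = sc.auc_above(cvm, cvt)
        modal_bin_mass = ff.frequencies_percent[int(np.floor(cvt))]
        assert abs(raw - binned_tail) <= modal_bin_mass + 1e-9


def test_analyze_volume_pipeline(small_mask):
    rng = np.random.default_rng(6)
    vol = sc.ActivityVolume(
        np.where(small_mask.data, rng.normal(100, 12, small_mask.shape), 0.0).clip(0),
        small_mask.voxel_pitch_mm,
    )
    result, cvm, ff = sc.analyze_volume(vol, small_mask, peel_layers=1)
    assert 0 <= result.auc_percent <= 100
    assert result.n_valid_cv == cvm.n_valid > 0
    assert result.peeled_volume_L < result.lung_volume_L
    # self-referential threshold: the volume's own modal CV
    assert result.cv_t_percent == pytest.approx(sc.modal_cvt([ff]))
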