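import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import spectcv as sc
from spectcv.errors import (
    ConsistencyError,
    DomainError,
    PackingError,
    SizingError,
)
from spectcv.phantom import hilum_point


class TestLungMask:
    def test_volume_and_topology(self, small_mask, small_spec):
        assert abs(small_mask.volume_L - small_spec.target_lung_volume_L) <= (
            0.02 * small_spec.target_lung_volume_L
        )
        structure = ndimage.generate_binary_structure(3, 1)
        assert ndimage.label(small_mask.data, structure=structure)[1] == 2

    def test_voxel_count_matches_volume_arithmetic(self, small_mask, small_spec):
        expected = small_spec.target_lung_volume_L * 1000 / 0.33**3
        assert abs(small_mask.voxel_count - expected) <= 0.02 * expected

    def test_deterministic(self, small_spec, small_mask):
        again = sc.build_lung_mask(small_spec)
        assert np.array_equal(again.data, small_mask.data)

    def test_grid_too_small_raises_with_required_extent(self):
        spec = sc.PhantomSpec(grid_shape=(32, 32, 32), voxel_pitch_mm=3.3)
        with pytest.raises(SizingError, match=r"\d+.*voxels"):
            sc.build_lung_mask(spec)


class TestLesionPlacement:
    def test_zero_occupancy_is_empty(self, small_mask):
        les = sc.LesionSpec(1.0, 0.5, 0.0)
        assert sc.place_lesions(small_mask, les).shape == (0, 3)

    @pytest.mark.parametrize(
        "diameter_cm,occupancy,placement",
        [
            (1.0, 0.10, "even"),
            (1.0, 0.12, "clustered"),
            (2.0, 0.10, "even"),
            (2.0, 0.48, "even"),
        ],
    )
    def test_occupancy_and_separation(self, small_mask, diameter_cm, occupancy, placement):
        les = sc.LesionSpec(diameter_cm, 0.5, occupancy, placement, seed=5)
        centres = sc.place_lesions(small_mask, les)
        _, occ, _ = sc.build_activity(small_mask, centres, les)
        assert abs(occ - 100 * occupancy) <= 0.5
        d_vox = diameter_cm * 10 / small_mask.voxel_pitch_mm
        dists = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() >= d_vox - 1e-6

    def test_lesion_voxels_stay_inside_lung(self, small_mask):
        les = sc.LesionSpec(2.0, 0.0, 0.10, seed=2)
        centres = sc.place_lesions(small_mask, les)
        act, _, _ = sc.build_activity(small_mask, centres, les)
        assert (act.data[~small_mask.data] == 0).all()

    def test_seed_reproducibility(self, small_mask):
        a = sc.place_lesions(small_mask, sc.LesionSpec(1.0, 0.5, 0.10, seed=9))
        b = sc.place_lesions(small_mask, sc.LesionSpec(1.0, 0.5, 0.10, seed=9))
        c = sc.place_lesions(small_mask, sc.LesionSpec(1.0, 0.5, 0.10, seed=10))
        assert np.array_equal(a, b)
        assert a.shape != c.shape or not np.array_equal(a, c)

    def test_clustered_is_compact(self, small_mask):
        even = sc.place_lesions(small_mask, sc.LesionSpec(1.0, 0.5, 0.10, "even", 3))
        clus = sc.place_lesions(
            small_mask, sc.LesionSpec(1.0, 0.5, 0.10, "clustered", 3)
        )
        hilum = hilum_point(small_mask)
        mean_r = lambda c: np.linalg.norm(c - hilum, axis=1).mean()  # noqa: E731
        assert mean_r(clus) < 0.6 * mean_r(even)

    def test_oversized_lesion_rejected(self, small_mask):
        with pytest.raises(DomainError, match="diameter"):
            sc.place_lesions(small_mask, sc.LesionSpec(30.0, 0.5, 0.05))

    def test_unreachable_occupancy_reports_achieved(self, small_mask):
        with pytest.raises(PackingError) as exc:
            sc.place_lesions(small_mask, sc.LesionSpec(2.0, 0.5, 0.70, "even", 1))
        assert 0 < exc.value.achieved_occupancy < 0.70


@pytest.fixture(scope="module")
def fine_mask():
    return sc.build_lung_mask(
        sc.PhantomSpec(grid_shape=(256, 256, 256), voxel_pitch_mm=1.65)
    )


class TestClinicalPitchLesionCounts:
    """Lesion counts at the 1.65 mm phantom pitch match volume arithmetic."""

    def test_fine_mask_volume(self, fine_mask):
        assert abs(fine_mask.volume_L - 4.2) <= 0.084

    def test_1cm_lesions_at_10_percent(self, fine_mask):
        les = sc.LesionSpec(1.0, 0.5, 0.10, "even", seed=3)
        centres = sc.place_lesions(fine_mask, les)
        # 0.10 * 4200 cm^3 / (pi/6 cm^3) ~ 802 spheres
        assert abs(len(centres) - 802) <= 80
        _, occ, _ = sc.build_activity(fine_mask, centres, les)
        assert abs(occ - 10.0) <= 0.5

    def test_2cm_lesions_at_48_percent(self, fine_mask):
        les = sc.LesionSpec(2.0, 0.5, 0.48, "even", seed=3)
        centres = sc.place_lesions(fine_mask, les)
        # 0.48 * 4200 cm^3 / 4.189 cm^3 ~ 481 spheres
        assert abs(len(centres) - 481) <= 48
        _, occ, red = sc.build_activity(fine_mask, centres, les)
        assert abs(occ - 48.0) <= 0.5
        assert abs(red - 24.0) <= 0.5


class TestActivity:
    def test_uniform_when_no_lesions(self, small_mask):
        act, occ, red = sc.build_activity(
            small_mask, np.empty((0, 3)), sc.LesionSpec(1.0, 1.0, 0.0)
        )
        assert occ == 0 and red == 0
        assert (act.data[small_mask.data] == 1.0).all()
        assert (act.data[~small_mask.data] == 0.0).all()

    def test_zero_activity_lesions_are_exactly_zero(self, small_mask):
        les = sc.LesionSpec(2.0, 0.0, 0.10, seed=4)
        centres = sc.place_lesions(small_mask, les)
        act, occ, red = sc.build_activity(small_mask, centres, les)
        vals = np.unique(act.data)
        assert set(vals) == {0.0, 1.0}
        assert abs(red - occ) < 1e-9  # zero lesion activity: reduction == occupancy

    def test_centre_outside_mask_rejected(self, small_mask):
        outside = np.argwhere(~small_mask.data)[0].astype(float)
        with pytest.raises(ConsistencyError):
            sc.build_activity(small_mask, outside[None], sc.LesionSpec(1.0, 0.5, 0.1))


class TestVentilationReduction:
    @pytest.mark.parametrize(
        "occ,act,expected",
        [
            (0.10, 0.50, 5.0),
            (0.12, 0.50, 6.0),
            (0.10, 0.00, 10.0),
            (0.12, 0.00, 12.0),
            (0.48, 0.50, 24.0),
            (0.48, 0.25, 36.0),
            (0.0, 0.37, 0.0),
        ],
    )
    def test_values(self, occ, act, expected):
        assert sc.total_ventilation_reduction(occ, act) == pytest.approx(expected)

    @given(
        occ=st.floats(0, 1, allow_nan=False),
        act=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounds(self, occ, act):
        red = sc.total_ventilation_reduction(occ, act)
        assert 0.0 <= red <= 100.0 * occ

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            sc.total_ventilation_reduction(1.2, 0.5)
        with pytest.raises(DomainError):
            sc.total_ventilation_reduction(0.5, -0.1)


class TestMotionBlur:
    def test_zero_amplitude_is_identity(self, small_mask):
        act = sc.ActivityVolume(small_mask.data * 1.0, small_mask.voxel_pitch_mm)
        out = sc.apply_motion_blur(act, 0.0, 0.0)
        assert np.array_equal(out.data, act.data)

    def test_total_activity_conserved(self, small_mask):
        act = sc.ActivityVolume(small_mask.data * 1.0, small_mask.voxel_pitch_mm)
        out = sc.apply_motion_blur(act, 12.0, 2.0)
        rel = abs(out.total_activity() - act.total_activity()) / act.total_activity()
        assert rel < 1e-3

    def test_point_source_axial_support(self):
        pitch = 3.3
        vol = np.zeros((64, 8, 8))
        vol[50, 4, 4] = 1.0
        amp = 16.5  # 5 voxels
        out = sc.apply_motion_blur(sc.ActivityVolume(vol, pitch), amp, amp)
        prof = out.data[:, 4, 4]
        nz = np.nonzero(prof > 1e-9)[0]
        support_mm = (nz.max() - nz.min()) * pitch
        assert abs(support_mm - 2 * amp) <= 2.5 * pitch

    def test_uniform_interior_unchanged(self):
        vol = np.ones((40, 6, 6))
        out = sc.apply_motion_blur(sc.ActivityVolume(vol, 3.3), 6.6, 6.6)
        assert np.allclose(out.data[10:30], 1.0, atol=1e-9)

    def test_basal_below_apical_rejected(self):
        act = sc.ActivityVolume(np.ones((8, 8, 8)), 3.3)
        with pytest.raises(DomainError):
            sc.apply_motion_blur(act, 2.0, 5.0)


class TestAttenuation:
    def test_tissue_values(self, small_spec, small_mask):
        mu = sc.build_attenuation(small_spec, small_mask)
        assert set(np.unique(mu.data)) <= {0.0, 0.04, 0.16}
        assert (mu.data[small_mask.data] == 0.04).all()
        assert mu.data[0, 0, 0] == 0.0
        body = (mu.data == 0.16)
        assert body.any()  # closed soft-tissue envelope exists
        # envelope surrounds the lung in-plane
        zc = small_mask.data.sum(axis=(1, 2)).argmax()
        row = mu.data[zc, small_spec.grid_shape[1] // 2]
        first_lung = np.nonzero(small_mask.data[zc, small_spec.grid_shape[1] // 2])[0]
        assert (row[: first_lung[0]] == 0.16).any()
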