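import pytest

import spectcv as sc
from spectcv import experiment as ex


@pytest.fixture(scope="session")
def small_spec():
    """Half-scale anatomy on a 48^3 grid: cheap structural test phantom."""
    return sc.PhantomSpec().scaled(0.5, grid_shape=(48, 48, 48))


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return sc.build_lung_mask(small_spec)


@pytest.fixture(scope="session")
def small_geometry():
    return sc.AcquisitionGeometry(
        n_angles=32, detector_pixel_pitch_mm=3.3, system_fwhm_mm=12.0
    )


@pytest.fixture(scope="session")
def desk_pair_result():
    """Desk-scale study of the normal vs the subtlest COPD distribution.

    20 + 20 Poisson realisations of the uniform lung and of the 1-cm /
    50% / 10%-occupancy evenly-lesioned lung, reconstructed and scored
    with a shared CV_T from the normal group.
    """
    dists = [
        d
        for d in ex.standard_distributions(1)
        if d.label in ("uniform", "1cm-50-10-even")
    ]
    return ex.run_experiment(ex.desk_scale_plan(1, dists, realisations=20))


@pytest.fixture(scope="session")
def mini_study_result():
    """All nine standard distributions at 4 realisations each."""
    return ex.run_experiment(ex.desk_scale_plan(1, realisations=4))
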