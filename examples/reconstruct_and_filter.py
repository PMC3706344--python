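"""OSEM reconstruction and Butterworth post-filtering of noisy projections.

Reconstructs one Poisson realisation of a uniform lung with 10 iterations
x 16 subsets, applies the 0.5 cm^-1 / order-3 Butterworth filter, and
prints how well the half-maximum segmentation of the result recovers the
true lung volume.
"""

import numpy as np

import spectcv as sc

spec = sc.PhantomSpec().scaled(0.5, grid_shape=(48, 48, 48))
mask = sc.build_lung_mask(spec)
activity = sc.build_activity(
    mask, np.empty((0, 3)), sc.LesionSpec(1.0, 1.0, 0.0)
).volume
geom = sc.AcquisitionGeometry(n_angles=32, detector_pixel_pitch_mm=3.3)
proj = sc.scale_to_counts(sc.forward_project(activity, geom), 1.0e6)
noisy = sc.poisson_realise(proj, seed=1)

settings = sc.ReconSettings()  # 10 iterations, 16 subsets
recon = sc.osem(noisy, geom, settings)
print(f"reconstructed {recon.shape} volume; OSEM voxel minimum "
      f"{recon.data.min():.2f} (the multiplicative update is non-negative)")
recon = sc.butterworth3d(recon, settings.butterworth_cutoff_cm,
                         settings.butterworth_order)

from spectcv.recon import butterworth_gain  # noqa: E402

for f in (0.0, 0.5, 1.0):
    print(f"filter gain at {f:.1f} cycles/cm: "
          f"{butterworth_gain(f, 0.5, 3):.4f}")

# the lung is defined on the *noiseless* reconstruction of the uniform
# reference, as in the study design
reference = sc.butterworth3d(sc.osem(proj, geom, settings))
segmented = sc.lung_from_reconstruction(reference)
print(f"half-max segmentation: {segmented.volume_L:.2f} L "
      f"vs true {mask.volume_L:.2f} L")
peeled, removed = sc.peel(segmented, 1)
print(f"peeling one edge layer removes {removed:.1f}% of the segmented lung,")
print("   excluding the partial-volume rind that would inflate CV values.")
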