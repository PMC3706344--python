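# Methods

This note documents the models behind `spectcv`: what each stage
computes, the assumptions and defaults, what the synthetic chain does and
does not emulate, and the numerical choices a maintainer would want
written down.

## The inhomogeneity statistic

For a reconstructed activity volume `f` and an analysis mask `M` (the
segmented lung minus peeled edge layers), the CV matrix is

    CV(v) = 100 · SD{ f(u) : u ∈ M, u ∈ K(v) } / mean{ ... }   [%]

for every voxel `v ∈ M`, where `K(v)` is a cubic kernel centred on `v`
(side 3 cm by default; at a pitch `p` the side in voxels is
`round(30 mm / p)` forced odd, e.g. 9 voxels = 729 samples at 3.3 mm).
The SD is the sample standard deviation (n−1); with ≥ 729 voxels the
difference from the population SD is far below every tolerance in use.
Kernel positions with fewer than 2 in-mask voxels or zero mean are
undefined. Out-of-mask voxels never enter any kernel: the statistic
measures intra-lung texture, not the lung boundary.

CV values are summarised as a *frequency function*: counts in half-open
bins `[k, k+1)` percent, normalised to sum to 100. The threshold CV_T is
the midpoint of the tallest bin of the *mean* frequency function of a
healthy reference group (ties break to the lower bin); `AUC(CV_T)` is
computed from the raw CV values with a strict `>`, not from the binned
histogram, to avoid bin-edge ambiguity. Both choices are contracts of
this implementation; the binned and raw tails agree to within one bin's
mass.

Because CV is scale-free, the score is invariant to the administered
activity and to global intensity calibration; because it is reported as
a percentage of all kernel positions, it is normalised per lung volume.

## Synthetic chain

**Phantom.** Two ellipsoidal lung fields with flattened medial faces and
a spherical diaphragm dome carved from each base, on an isotropic voxel
grid. A global scale factor is bisected so the lung volume matches the
target (4.2 L for the life-size thorax of a 65-year-old male) to within
0.5% (contract ±2%). The geometry is a surrogate: the analysis method is
geometry-agnostic, so only volume, the two-lobed topology and an
apex–base axis matter.

**Lesions.** Ventilation defects are non-overlapping spheres (centre
distance ≥ diameter) whose rasterisation is the voxel-centre-in-sphere
rule; spheres may be clipped by the lung boundary and only in-lung
voxels count towards occupancy, which is accounted in voxel units and
held within ±0.5 percentage points of target. "Even" placement is seeded
rejection sampling, quasi-uniform over the lung; above 30% occupancy —
where random sequential packing jams near 38% — placement falls back to
a randomly offset face-centred-cubic lattice (bulk coverage 74%).
"Clustered" placement fills a compact region grown around a fixed
main-bronchi landmark (mid-sagittal, centroid depth, 45% of the
apex–base extent); only the cluster's surface against normal lung, not
its position, drives the score. The functional loss of a distribution is
`100 · occupancy · (1 − relative lesion activity)` percent.

**Respiratory motion.** A time-averaged axial displacement
`A(z)·sin(phase)` over a full cycle, with `A` linear from the apical to
the basal amplitude (defaults 2 mm and 20 mm at life size — a typical
tidal diaphragm excursion — scaled with the anatomy). A Jacobian weight
compensates the compression of the displacement field so total activity
is conserved to <0.1%. Heartbeat motion is not modelled.

**Projector.** Idealised parallel beam: each projection is the ray sum
of the volume rotated about the axial axis, convolved in the projection
plane with a Gaussian of FWHM 12 mm (mid-range of a LEHR system's
1–1.5 cm resolution). Rays are sampled on a regular grid with bilinear
interpolation; the per-angle operators are precomputed sparse matrices
whose columns are normalised so every in-FOV voxel contributes exactly
its activity to each view (activity conservation per projection is then
exact). Backprojection is the exact adjoint. Attenuation, when enabled,
uses midpoint-weighted line integrals of the attenuation map
(lung 0.04 cm⁻¹, soft tissue 0.16 cm⁻¹, air 0); scatter is neither
simulated nor corrected, keeping the chain self-consistent. Projections
are globally rescaled to a count budget and Poisson noise is drawn
pixel-wise.

**Reconstruction.** Ordered-subset EM, 10 iterations × 16 subsets by
default; angles are assigned to subsets by stride and processed in
bit-reversed order; the initial estimate is uniform inside the
cylindrical field of view; zero-sensitivity voxels stay zero. The OSEM
system model matches the projector, including the Gaussian system blur
(the counterpart of clinical collimator-detector-response compensation);
`model_system_blur=False` gives the plain unmodelled-blur variant, in
which a reconstructed point source has FWHM ≈ the system blur, while the
default recovers resolution (FWHM below the system blur). Volumes are
post-filtered with a radially symmetric 3-D Butterworth filter,
|H(f)| = [1 + (f/f_c)^(2n)]^(−1/2), f_c = 0.5 cm⁻¹, n = 3 ("power 6"),
applied in physical frequency units; DC is preserved exactly.

**Segmentation.** For phantom studies, the lung is the set of voxels
strictly above half the maximum of the noiseless reconstruction of the
uniform reference. For attenuation/CT volumes, voxels below 0.12 cm⁻¹
inside the body envelope, with border-touching air components discarded
and the two largest components kept (optional seed points make the
choice explicit). One voxel layer is then peeled off by 6-connected
morphological erosion — exactly the voxels with an out-of-mask face
neighbour — to exclude the partial-volume rind whose high CV reflects
the boundary, not ventilation.

## The desk-scale study

`experiment.desk_scale_plan` reproduces the simulated normal-vs-COPD
design at desk scale: per distribution one noiseless projection set, 20
Poisson realisations reconstructed and analysed, CV_T from the normal
group's mean frequency function, AUC(CV_T) per realisation, and exact
Mann–Whitney comparisons of each lesioned group against the normal.
Seeds derive deterministically from (master seed, distribution label,
realisation index), so a plan is bit-reproducible.

The reduction strategy keeps every quantity the CV statistic is
sensitive to at its clinical value and shrinks only the anatomy:

- grid 64³ at the clinical 3.3 mm pitch; thorax geometrically similar at
  64% linear scale (1.1 L lungs) — the largest that fits the field of
  view;
- lesion diameters, system blur, kernel size (729 voxels), filter,
  OSEM settings and the one-voxel peel unchanged;
- 64 angles over 360° (half the clinical 128);
- the count budget is set so the mean of high-count projection pixels
  (above half maximum in the normal's noiseless projections) is
  (100/15)² ≈ 44 counts, i.e. ≈15% Poisson pixel CV — the clinical noise
  regime. An angle-proportional total-count policy is available as an
  alternative, but at reduced projected area the two anchors diverge and
  the noise regime is the one the texture statistics respond to.

What the smaller lung costs is sample size, not physics: ~19,000 valid
kernel positions per volume instead of ~90,000, so per-realisation
AUC(CV_T) scatter is a few percentage points rather than ~2, and the
edge-adjacent fraction of the lung is larger. The full clinical scale is
available (`anatomy_scale=1.0, grid=(128,)*3, n_angles=128`) at ~8× the
cost per reconstruction.

## What the synthetic chain does and does not emulate

Emulated: two-lobed lung anatomy at the target volume; packed spherical
ventilation defects with controlled occupancy, contrast and clustering;
system-resolution blur; clinical per-pixel count statistics; respiratory
basal motion; OSEM + Butterworth processing; half-max lung definition
and edge peeling.

Not emulated: anthropomorphic anatomy (airways, vasculature, ribs,
posture), Monte-Carlo photon transport (scatter, septal penetration,
energy windows), non-circular camera orbits and depth-dependent
collimator response, attenuation in the simulated-study default (the
clinical chain both degrades and ideally corrects; omitting both sides
is the matched idealisation), and hot spots from central-airway
impaction seen in advanced COPD.

Two consequences matter when reading test results against clinical
experience. First, the idealised chain lacks the noise amplification of
scatter/attenuation corrections, so at matched pixel noise its
reconstructed noise CV is roughly half that of a clinical chain, and the
CV frequency function is correspondingly narrower (mode near 10% rather
than ~20%). Second, with a 1%-bin histogram and a narrow frequency
function, the AUC at the modal midpoint is sensitive to where the mode
bin happens to fall relative to the median: the healthy self-score is
stable for a fixed configuration (≈48% here) but its distance from the
nominal ~52% is dominated by that bin alignment rather than by any
pipeline defect. Group *comparisons* at a shared CV_T — the method's
purpose — are unaffected: the subtlest standard defect (5% functional
loss) separates from normal with U ≈ 0 at 20 + 20 realisations.

Respiratory motion in this chain is pure time-averaged blurring. It
raises basal CV relative to the motionless lung deterministically; under
resolution-modelled OSEM, however, edge overshoot at the *sharp* apical
boundary can mask the basal elevation in noisy single realisations, so
that property is demonstrated with the plain OSEM model.

## Group statistics

Mann–Whitney U comparisons are two-tailed; the exact null distribution
is used when n₁·n₂ ≤ 400 and no value is shared between the groups
(ties *within* one group leave the enumeration intact — relevant for
saturated AUC groups at 100%), otherwise the tie-corrected normal
approximation with continuity correction. Group summaries report the
sample SD and a Student-t 95% confidence half-width,
`t(0.975, n−1)·SD/√n`; with five subjects per group the t convention
(not normal-z) reproduces the reference cohort's printed ±13%.

## Degenerate inputs and tie-breaks

- Phantoms that cannot fit the grid raise a sizing error naming the
  required extent; unreachable occupancies raise a packing error with
  the achieved value.
- Projection scaling of an all-zero set, segmentation of an all-zero
  volume and CV analysis of an empty matrix are errors, not silent
  zeros; peeling that empties a mask reports the layer at which it died.
- Modal-bin ties break to the lower bin; AUC uses strict `>`; kernel
  sides round to the nearest odd voxel count.
- All randomness flows through numpy Generators seeded from explicit
  integers; derived seeds stay below 2³¹.

## Known limitations

The phantom's smooth uniform background makes the healthy reference
*more* homogeneous than real lungs (gravity gradients, bronchial tree),
so absolute CV_T and AUC levels are chain-specific and should not be
compared numerically against clinical values — only the ordering and
separation behaviour transfers. Lesion density equals lung density, so
the attenuation map carries no lesion contrast. The clustered placement
is one plausible reading of "central, near the main bronchi"; cluster
positions elsewhere in the lung are not explored. Very large kernels on
small lungs leave few valid positions; the kernel side is exposed but
the double-peaked frequency functions reported for ≥3.6 cm kernels in
some settings are not reproduced here.
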