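# Methods

This note documents the models, conventions and numerical choices behind
`radstab`, and what the synthetic experiments do and do not establish.

## Phantom model

Nodules are spheres with class-dependent attenuation on a lung-like
background of −850 HU: solid (SN) nodules are uniform at +60 HU, pure
ground-glass (pGGN) at −500 HU (strictly between background and solid, hence
a lower contrast-to-noise ratio), and part-solid (pSN) nodules combine a
ground-glass shell with a solid core at `core_fraction` (default 0.5) of the
radius. Additive white Gaussian noise (default sd 20 HU) stands in for CT
quantum noise. There is no point-spread blurring: the noise-free phantom is
exactly two-valued, which keeps the voxel-level contracts of the generator
testable. The reference mask is the set of voxels whose centers fall inside
the sphere.

Default grid: 64×64×32 voxels at 1 mm isotropic spacing (an axial crop
around a nodule at thin-slice reconstruction); the sampler enlarges the grid
for nodules that would touch the boundary. Diameters follow a log-normal
with median 0.56 cm and IQR 0.40 cm, truncated to (2 mm, 30 mm) — lesions of
3 cm and above are excluded by construction — and the class mix defaults to
34.9% SN / 17.2% pSN / 47.8% pGGN (81/40/111 in 232).

## Observer model

An observer's mask is obtained by thresholding the signed Euclidean distance
transform d(x) of the reference (positive inside, mm) against a smooth
Gaussian random field:

    perturbed = { x : d(x) + bias_mm + jitter_mm · g(x) > 0 }

where g is unit-variance low-pass-filtered white noise with correlation
length `smoothness` (default 1.5 mm). This family was chosen because it
gives near-linear control of the boundary offset in physical units,
guarantees closed regions, and separates systematic over/under-segmentation
(`bias_mm`) from random boundary roughness (`jitter_mm`). Only the largest
26-connected component is kept — an observer delineates a single lesion —
and a perturbation that leaves fewer than 2 voxels is retried with halved
jitter (5 attempts).

Two numerical details matter:

* **Surface anchoring.** The voxel-center EDT measures center-to-center
  distances, which over-counts distance to the digitized *surface*. The zero
  level is re-anchored by subtracting 0.3 of the mean spacing — chosen
  between the face-neighbor offset (0.5) and the lattice-diagonal average —
  so a +1 mm bias dilates a 10 mm sphere by 1 mm to within the voxelization
  error (verified against direct voxel-count oracles at 1.0 and 0.5 mm
  spacing).
* **Correlation length.** At `smoothness` much larger than the nodule the
  field degenerates to a random global offset and the per-seed Dice
  distribution becomes strongly right-skewed (many draws ≈ 1); 1.5 mm keeps
  mean and median Dice within ~0.01 of each other and produces per-observer
  Dice IQRs around 0.10–0.15, the range seen in multi-reader studies.

`calibrate_profile_to_dice` bisects on `jitter_mm` until the mean Dice over
20 seeded simulations is within ±0.02 of a target, and reports the
attainable range when the target is infeasible. The default 7-observer panel
is one perfect reference (the senior reader anchoring all comparisons) plus
six profiles calibrated to Dice 0.75, 0.76, 0.80, 0.72, 0.66 and 0.69
against a solid phantom at the cohort's median diameter.

Dice depends only on masks, so the harder-to-see ground-glass boundary is
made operational as a per-class jitter multiplier (pGGN ×1.25, configurable)
rather than through image contrast; this reproduces, by construction, the
empirical ordering pGGN < SN/pSN in segmentation agreement. Smaller nodules
are automatically harder: a fixed-amplitude boundary perturbation removes a
larger volume fraction of a small sphere, giving the positive
diameter–Dice association without any extra mechanism.

## Feature catalogue

1,246 features over 14 image types: the original image contributes 18
first-order + 14 shape + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM = 102;
each of the 5 LoG scales and 8 wavelet sub-bands contributes the 88
intensity/texture features (shape is a property of the mask alone and is
computed once). Feature definitions follow the standard radiomics reference
set. Conventions, all configurable:

* **Discretization**: fixed bin width of 25 intensity units anchored at the
  in-mask minimum, on every image type (filtered intensities included).
  Fixed bin *count* is deliberately not used.
* **Texture geometry**: 13 unique direction vectors at Chebyshev distance 1;
  GLCM symmetrized and normalized per direction with per-direction feature
  averaging; GLSZM zones and GLDM neighborhoods are 26-connected; GLDM
  dependence tolerance α = 0. GLRLM/GLSZM/GLDM column indices start at 1
  (GLDM column j holds dependence j−1).
* **Moments**: population (1/n) throughout, so the CCC reduction identities
  are exact.
* **Shape**: marching-cubes mesh at the 0.5 iso-level of the mask after a
  0.7-voxel Gaussian pre-smoothing — the raw binary mesh overestimates a
  sphere's area by ~8% (staircase artifact), the smoothed mesh reports
  sphericity ≈ 0.99 at <3% mesh-volume cost; tiny masks that smooth below
  the iso-level fall back to the raw mesh. Axis lengths are 4·√eigenvalue of
  the physical voxel-center covariance; maximum diameters are the largest
  pairwise surface-vertex distances in 3D and in the three coordinate-plane
  projections.
* **Filters**: LoG at σ ∈ {1, 2, 3, 4, 5} mm, spacing-aware (per-axis sigma
  in voxels), kernel truncated at 8σ so a constant volume maps to numerical
  zero; σ = 1 mm at 1 mm spacing is mildly under-sampled (discrete-kernel
  aliasing ~1e-5 relative), which is inherent to that scale. Wavelets:
  single-level stationary (undecimated) Coiflet-1 with periodic boundary;
  sub-band letters ordered (x, y, z). The transform requires even extents;
  the pipeline always filters the full (even) grid before cropping, so this
  never constrains normal use.
* **Degenerate values** become NaN with a warning, never an exception — one
  pathological nodule cannot abort a study — and NaN-bearing features are
  excluded from OCCC with an itemized report. Known case:
  `RobustMeanAbsoluteDeviation` is NaN on 2-voxel masks (the [P10, P90]
  subset is empty). GLCM on a single-level ROI uses documented fallbacks
  (Correlation 1, Imc1/Imc2 0, MCC 1).
* **Normalization** before extraction defaults to `none`: HU are already
  calibrated and fixed-bin-width discretization on raw intensities is the
  standard convention; `unit_range` and `zscore` are available behind
  `FeatureConfig.normalize_mode`.

Every texture matrix is verified in the test suite against independent
brute-force counters (triple-loop pair counting, line walking, BFS flood
fill, neighbor counting) with exact integer agreement, and first-order
features against a direct-summation oracle at 1e-9.

## Agreement statistics

* **Dice** 2|A∩B|/(|A|+|B|); both-empty is an error, not 1.
* **Diameter**: on the axial slice with the largest in-plane extent, the
  mean of the maximum long diameter and the maximum perpendicular short
  extent, in cm; center-to-center measurements are extended by half an
  in-plane voxel and floored at one voxel. Slice ties go to the lowest
  index.
* **ICC** is fixed to the two-way random-effects, absolute-agreement,
  single-measure form ICC(2,1) with the F-based 95% CI, cross-checked
  against pingouin in the tests. Zero between-subject variance returns 0
  with a warning (agreement is meaningless there, not perfect).
* **OCCC** uses population moments; for J = 2 it equals Lin's CCC to
  machine precision, and in general equals the variance-weighted average of
  the pairwise CCCs (a tested identity). It can be negative for discordant
  columns; negative values are reported as computed and classified poor,
  not clamped. All-constant identical columns give 1; all-constant
  differing columns give 0.
* **Stability classes**: poor < 0.5 ≤ average < 0.75 ≤ good < 0.90 ≤
  very good; boundaries inclusive on the upper class.

## Study design and reporting

One OCCC per feature per study: rows are nodules, columns the J observers —
the design appropriate for consistency across large samples with three or
more observers. A per-nodule-type recomputation serves the subgroup
comparison. The per-nodule segmentation summary is the median of the
J(J−1)/2 pairwise Dice values; per-observer tables report Dice against the
reference reader. Subgroup stability comparisons use Kruskal–Wallis across
groups with pairwise rank-sum post-hocs under Bonferroni adjustment
(rank-sum chosen to match the nonparametric omnibus test). Whether the
OCCC panel includes the automatic observer is configurable — the default
panel uses all seven groups.

## Problem sizes

The test suite runs the end-to-end monotonicity experiment at 4 calibrated
agreement levels × 30 phantoms (32³ grids) × 5 observers, and the
acceptance script a 60-nodule × 7-observer study on the default grid —
desk-scale stand-ins for the 232-nodule cohort, sized so a full run takes
minutes on a single CPU while leaving the OCCC medians well separated
between conditions.

## What the synthetic study does not show

The phantoms are homogeneous spheres: they carry no intra-nodular texture
heterogeneity, spiculation, vascular attachment or partial-volume blur, so
absolute stability rates (e.g. the share of features with OCCC ≥ 0.75) are
properties of this synthetic cohort and should not be read as estimates for
clinical CT data. What does transfer is structural: the catalogue
bookkeeping, the algebraic behavior of the agreement statistics, and the
qualitative findings that feature stability falls as segmentation agreement
falls, that ground-glass nodules are less stable than solid ones under a
harder boundary, and that smaller nodules segment less consistently.
Observer error is a modeling choice here (smooth boundary fields), not an
estimate of real readers' error structure.
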