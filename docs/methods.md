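# Methods

## Model and assumptions

`rodcone` relates outer-nuclear-layer thickness on OCT (ONL throughout
meaning the combined Henle fiber layer + ONL + myoid zone, since the
HFL is largely photoreceptor axons and the myoid zone inner segments)
to the proportional survival of rods and cones. The model rests on
four assumptions:

1. ONL thickness at a location is proportional to the surviving
   photoreceptor complement there; a healthy eye has 100 % survival and
   exhibits the *normal thickness* `T_normal`.
2. Rod and cone somata contribute equally to ONL thickness at any given
   location, so only the local composition `P_rods` (with
   `P_cones = 1 − P_rods`) matters, not absolute densities — relative
   composition is far more consistent across individuals than absolute
   density.
3. Rods and cones are the only cell classes contributing (Müller glia
   extensions are neglected).
4. Survival is global: one `(S_cones, S_rods)` pair for the whole
   macula. Diseases with strongly patchy or sectoral loss violate this;
   the two-region estimate is then a weighted average.

Under these assumptions thinning is exactly linear:
`T_simulated = T_normal · [(1 − P_rods)·S_cones + P_rods·S_rods]`.
Nonlinear effects — gliosis, edema, age-related thickening, outer-band
(EZ/IZ) disruption — are deliberately out of scope.

## Reference-model construction

**Projection.** Histologic densities are tabulated in spherical retinal
coordinates (longitude, colatitude about the foveal pole). We flatten
them with an azimuthal-equidistant projection, `r = R·colatitude`,
which preserves arc length along every meridian and has a single
parameter, the model-eye retinal radius `R` (default 12.0 mm, the
conventional posterior-pole radius of curvature; configurable). At
macular eccentricities (≤ 4 mm ≈ 19° colatitude) the choice of
projection perturbs positions by well under the inter-sample spacing.

**Registration.** Source (canonical left-eye, fovea at origin, +x
toward the disc) and target (scan raster) frames each carry two
landmarks, fovea and optic-nerve center. The registration is the unique
direct similarity — translation, rotation, isotropic scale, four
degrees of freedom fixed exactly by the two landmark pairs — computed
as a complex-affine map; for right-eye targets the source is first
mirrored across the vertical axis through its fovea. The transform is
exact at the landmarks and exactly invertible. The default source disc
position is colatitude 22° on the horizontal meridian, which at
R = 12 mm puts the disc 4.6 mm from the fovea, the anatomic norm.
Registered sample positions may fall outside the raster; they are kept
(they still support interpolation at interior pixels) rather than
clipped.

**Interpolation.** Scattered densities are interpolated at every
A-scan position on a Delaunay triangulation. The default is
piecewise-linear: deterministic, exact at the sampling points, and
reproducing affine fields inside the convex hull (both properties are
regression-tested at 1e-9). A C1-smooth Clough–Tocher variant
(`method="smooth"`) is selectable when visually smooth density maps
matter; it shares node-exactness and linear precision. Outside the
convex hull nothing is extrapolated — pixels are flagged invalid and
stay missing through the whole pipeline. Negative interpolated values
(possible for the smooth variant) are clamped to 0 and counted, since
densities are physical.

**Proportions.** `P_rods = rods/(rods+cones)` per A-scan; pixels with
zero total density or outside support are *missing*, never NaN leaking
into statistics. Missingness propagates: simulated thickness is missing
where composition is, and every regional mean is taken over valid
pixels only.

## ETDRS regions

Grid diameters default to the universal clinical convention 1 / 3 / 6 mm
(configurable); the grid centers on the fovea. Membership is a
pixel-center point-in-region test in millimetres, honouring anisotropic
spacing; no partial-area weighting — the rasterisation error vanishes
with pixel size and is covered by an area-convergence test. The outer
ring is one annulus rather than four subfields, which makes its mean
invariant to rotation about the fovea (verified to < 0.1 µm under
bilinear resampling on radially symmetric maps; the test tolerance is
0.5 µm to cover resampling error). The inner ring mask is computed but
unused by the default analysis, which deliberately skips the
cone-to-rod transition zone where composition varies most between
individuals. A ring extending past the scan border is truncated with a
warning and a flag; with the default 61×512 @ 0.06×0.012 mm protocol
the 6 mm ring is vertically truncated, which is the realistic situation
for that field of view.

## Inversion

The exact 2×2 solve is primary; the survival-grid lookup
(`method="grid"`) is an independent cross-check that reconstructs the
affine regional-mean surfaces from the simulated lattice and inverts
them — because the surfaces are exactly affine in the survival pair,
the global affine fit equals per-cell bilinear inverse interpolation to
floating point, and the two routes agree to 1e-6 everywhere unclamped.
A condition-number guard (default 1e6, far above the ~1.8 of realistic
topography) raises a non-identifiability error when the two regions
have effectively identical composition, the case where the two-region
system genuinely has no unique solution. Out-of-box solutions are
replaced by box-constrained least squares (`scipy.optimize.lsq_linear`,
BVLS) rather than raw truncation, preserving a defined optimality
criterion; clamped parameters are flagged and the thickness residual
reported. With two equations and two unknowns the unclamped residual is
zero by construction, so a nonzero residual is itself a diagnostic that
the observation lies outside the attainable parallelogram.

## B-scan simulation

Per A-scan the target ONL voxel count is
`round(T_normal · P_simulated / dz)`, nearest integer with ties away
from zero, capped at the column's current count. Exactly
`current − target` voxels are removed at uniformly random depths within
the layer (uniformity is chi-square-tested); the same number is
inserted at uniformly random depths into the vitreous with intensities
resampled with replacement from that column's own vitreous, so total
column length is conserved exactly and interfaces above the edited
layer shift down by the removed count while those below are unchanged.
A master seed spawns one substream per (B-scan, A-scan) column, keyed
by indices, making results reproducible and order-independent. Columns
with missing composition are left unedited. Removal positions are
assumed uniform; no speckle statistics or outer-band disruption are
modeled — the simulation reproduces thickness, not texture pathology.
When simulating from a volume, the reference's normal thickness should
be the volume's own segmented ONL (`thickness_map_um("ONL")`) so that
targets and current counts agree exactly at full survival.

## Synthetic data

The generator emulates the qualitative topography of human
photoreceptors with smooth parametric profiles (exponential cone decay
from a foveal peak over a floor; Gaussian rod ring with a rod-free
foveal zone; Gaussian ONL bump). Defaults — cone peak 190 000 cells/mm²
decaying with a 0.6 mm scale over a 4 000 floor; rod peak
160 000 cells/mm² in a ring at 4.0 mm (σ = 1.8 mm) with a 0.2 mm
rod-free radius; ONL 110 µm at the fovea falling to 60 µm
(σ = 1.2 mm) — are magnitudes consistent with published human
topography, not literature values asserted as ground truth, and are all
configurable. Sampling points lie on a jittered Fermat spiral out to
10 mm plus the foveal center and a tight rod-free octagon around it, so
the interpolated rod density at the fovea is exactly zero and the
convex hull covers any macular raster. The default scan protocol
(61 B-scans × 512 A-scans, 0.06 × 0.012 mm, 496 voxels at 3.87 µm)
mirrors a common commercial macular volume — cosmetic fidelity only.
Synthetic cohorts draw per-patient survival uniformly from configured
ranges (controls fixed at (1, 1)) and add Gaussian noise to the
regional means.

What the synthetic data does *not* emulate: measured (non-parametric)
density topography, inter-individual variability of composition,
segmentation error, speckle, eye-motion artifacts, or patchy loss.
Passing tests therefore demonstrate the mathematical correctness and
numerical behaviour of the pipeline, not clinical accuracy on real
scans.

## Numerical choices and problem sizes

- Full survival takes an exact short-circuit so the healthy identity is
  bit-for-bit, immune to floating-point round trip through the product.
- Rounding of voxel targets: half away from zero.
- The linear solve falls back to the box only when a parameter leaves
  [0, 1] by more than 1e-9; smaller excursions are clipped silently.
- Survival-grid step defaults to 0.25 (a 5×5 lattice, enough to pin the
  affine surfaces exactly); the recovery lattice in the verification
  scripts is 21×21.
- Verification runs use a 65×65 @ 0.1 mm isotropic raster (contains the
  full ETDRS grid) for regional statistics and inversion, the full
  61×496×512 protocol for volume editing, and 500-patient cohorts per
  noise level {4, 2, 1, 0} µm; the whole verification suite completes
  in seconds on one CPU, so these sizes are comfortable defaults rather
  than compromises.

## Known limitations

- Global-survival assumption (above); per-A-scan survival maps are a
  natural extension but not implemented.
- No uncertainty intervals on the estimates; the residual and clamping
  flags are the only diagnostics.
- The two-region system is exactly determined, so measurement noise
  propagates directly into the estimate (≈ 0.01–0.02 median absolute
  survival error per µm of regional noise at the default topography).
- Landmarks are inputs; no automatic fovea or disc detection.
- Real-scan ingestion expects already-segmented thickness maps or
  surfaces; proprietary raw formats and layer segmentation are out of
  scope.
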