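# Methods

This note documents the models, estimators and numerical choices behind
`dermakin`, and what its synthetic validation does and does not establish.

## Coordinate and data conventions

Volumes are indexed `(x, y, z)` with x the loading direction and z depth;
TIFF page *k* is the slice `data[:, :, k]`. Voxel sizes are in micrometres
and may be anisotropic — the nominal acquisition grid is 1.144 × 1.144 ×
1 µm — and every geometric computation (window displacements, warps, feature
positions fed to strain estimation) is carried out in physical µm, not voxel
units. Intensities are normalized by the fluorescein reference tabulated for
the acquisition channel, laser power and detector gain (pointwise division;
exact-match lookup, no interpolation between settings). Only ratios between
conditions are meaningful downstream, which is all the normalization needs
to preserve.

## Segmentation

The tissue mask thresholds the summed normalized intensity of all emission
channels at its overall mean (ties inclusive, so a constant volume is wholly
tissue — the deterministic total choice). The collagen mask is a named
plug-in applied slice-wise and restacked; the default `threshold-otsu`
computes one Otsu threshold per volume so all slices share a scale, and any
callable `slice -> bool mask` (for example an external CNN classifier) can
be substituted — downstream code needs only the boolean mask. The
collagen-positive fraction uses tissue-positive voxels as the denominator
and collagen ∧ tissue as the numerator.

## Fiber orientation and directional variance

Per-voxel 3D fiber orientation is estimated from a 7 × 7 × 7-voxel window by
a weighted summation of direction dyads. The default forms the **gradient
structure tensor**: Gaussian-derivative gradients at a fixed physical scale
(`grad_sigma_um = 0.8` µm, about half the default phantom fiber radius;
isotropic in µm on the anisotropic grid), their dyads summed over the
window; since gradients lie in the plane normal to a fiber, the axis is the
*smallest*-eigenvalue eigenvector. Two displacement-based variants
(`"centroid"`: the window's intensity-inertia principal axis; `"center"`:
intensity-weighted dyads of unit displacement axes from the centre voxel)
are kept behind the same contract. The gradient form is the default because
the displacement forms degrade whenever a window contains a second, parallel
fiber — on a perfectly aligned multi-fiber phantom the centre-displacement
variant yields DV ≈ 0.24 instead of 0 — while gradients from *any* number of
parallel fibers still span only the normal plane. The derivative scale was
calibrated on phantoms with known per-voxel axes: 0.8 µm minimizes the
disagreement between image-based and axis-transport directional variance
across concentrations κ ∈ {0, 8, 32}; coarser scales over-merge neighbouring
fibers, finer scales admit voxelization noise.

Angles are reported axially: θ ∈ [−90°, 90°) in the X-Y plane, φ ∈ [−90°,
90°] out of plane, with (θ, φ) and its antipode identified. Voxels whose
window leaves the volume are invalidated, never padded; the centre voxel
contributes no displacement axis; the field is invariant to uniform
intensity rescaling.

Directional variance condenses the valid axes u into

DV = (3/2)(1 − λ_max(⟨u uᵀ⟩)), clipped to [0, 1],

which is 0 when all axes coincide, 1 for axes uniform on the sphere (the
isotropic orientation tensor is I/3), rotation-invariant and antipodally
invariant. The dyadic formulation is the simplest statistic satisfying those
endpoint and invariance constraints for axial data; any alternative with the
same contract could be swapped behind `directional_variance`.

## Feature tracking and micro-scale strain

Trackable SHG features are local maxima of the minimum eigenvalue of the
image structure tensor (Shi-Tomasi corners in 3D), restricted to the
collagen mask and to positions where the tracking patch (20 × 20 × 5 voxels,
shallow in z to match the anisotropic point-spread function) and search
window (20 × 20 × 20) fit, greedily non-max-suppressed at a minimum spacing,
deterministically ordered (score, then lexicographic position). Tracking is
incremental normalized cross-correlation: the template comes from the
previous increment's volume at the previous position, matched over the
search window in the current volume; the sub-voxel peak is a least-squares
paraboloid over the 3 × 3 × 3 correlation neighbourhood (falling back to
separable quadratic fits at borders). A correlation of exactly 1 means
identical patches, so refinement is skipped there and the integer peak
returned. Tracking-quality gating is forward-backward: each new position is
tracked back one increment and compared with the stored position
(incremental error); after the final increment a fresh template at the final
position is tracked back through all increments to the reference (overall
error). A feature is well-tracked iff every incremental error < 10 voxels
and the overall error < 1 voxel, both strict. The backward template is taken
at the final tracked position itself rather than re-detected from corners:
re-snapping to the nearest corner would offset the backward trajectory by
the snap distance and turn the 1-voxel overall gate into a test of detector
geometry rather than tracking consistency.

From all well-tracked points, the largest-volume tetrahedron (exhaustive
C(n, 4) enumeration up to n = 25, restricted to convex-hull vertices above
that — the maximal tetrahedron's vertices are extreme points, so nothing is
lost) defines the 3D deformation gradient by solving the edge-vector system
[d₁ d₂ d₃] = F [r₁ r₂ r₃] in physical µm; translation cancels by
construction. Green strain ε = ½(FᵀF − I), its principal decomposition and
V/V₀ = det F follow. A single tetrahedron is used deliberately — it is the
least-squares-free, assumption-free estimate from the most widely spaced
material points — at the cost of sensitivity to individual vertex error;
the paraboloid refinement exists chiefly to keep that error well under a
voxel.

Volume-to-volume drift is removed beforehand by 3D phase correlation
(`register_translation`); the returned vector is the displacement of the
moving volume relative to the reference (so aligning means shifting by its
negative).

## Macro-scale mechanics

Fiduciary dots are tracked by 2D NCC with the same incremental-template and
sub-pixel logic. The 2D deformation gradient comes from an isoparametric
4-node bilinear quad fitted to the marker positions, evaluated at the
element centroid (nodes ordered counter-clockwise about the reference
centroid; the bilinear map reproduces affine deformations exactly); with
more than four markers a least-squares affine fit is used. Engineering
stress divides the equilibrium load by the optically measured undeformed
cross-section; the incremental modulus is the backward difference of stress
over ε_xx from increment 1, and the incremental Poisson's ratio is
−ε_yy/ε_xx. The reference configuration is the post-preconditioning,
pre-stressed state in which the imaging reference volume is taken; strain is
zero there by definition.

Scalars are tabulated at three stretch landmarks: 10 % and 20 % ε_xx by
linear interpolation between bracketing increments (quantities that only
exist at whole image volumes, like DV, take the nearest increment instead —
volumes exist only at increments), and the increment of maximum defined
modulus (no interpolation; it typically directly precedes failure).
Landmarks outside the observed strain range are reported missing, never
extrapolated. Micro-scale quantities are tabulated against micro-scale
ε_xx, macro against macro.

## Affine comparison

The measured F at a landmark is applied to the reference volume as a pure
affine resampling about the volume centre (composed in physical µm;
trilinear interpolation by default, nearest-neighbour available for masks;
zero fill outside). The collagen mask of the warped volume is *recomputed*
by the same segmenter, not warped from the reference mask, and the
orientation field and DV follow identically. ΔDV = DV_measured − DV_affine;
positive values mean the affine model over-predicts realignment. For F = I
the warp is an exact identity, so ΔDV = 0 holds exactly when the measured DV
comes from the same pipeline.

## Statistics

Metrics with several image volumes per tissue sample are compared between
groups by a nested one-way ANOVA: F = MS(group)/MS(sample within group) with
degrees of freedom (g − 1, Σ(s_g − 1)) — the expected-mean-squares test,
exact for balanced designs (where it coincides with a one-way ANOVA on
per-sample means, used as the independent cross-check in the tests) and the
standard approximation otherwise. Measured type-I error over 1000 balanced
null simulations (2 groups × 6 samples × 3 volumes) is 0.047 at α = 0.05.
Sample-level metrics use two-sided unpaired Student (equal-variance)
t-tests — "Student" read literally, not Welch — and ΔDV is tested against
zero with a one-sample t-test. Significance is p < 0.05. Box summaries use
type-7 (linear-interpolation) quartiles, whiskers at the min/max of
non-outliers, outliers beyond 1.5 IQR from the box; constant data yield a
zero-width box. Degenerate zero-variance comparisons are reported as limits
and flagged rather than raised.

## The phantom generator

Phantoms exist to give every stage a recoverable answer, not to imitate
dermal texture. Fibers are straight cylinders spanning the volume with a
Gaussian radial profile (σ = fiber_radius/2, i.e. intensity e⁻² at the
nominal radius), rendered additively in physical µm and sampled onto the
anisotropic grid; axes are drawn from a von Mises–Fisher distribution about
the mean axis and antipodally symmetrized (fibers are axes, not arrows),
with κ = 0 the uniform axial distribution and κ = ∞ fully aligned. The TPEF
channel is a fixed fraction of the SHG fiber signal; noise is additive
Gaussian clipped at zero. One integer seed drives a single generator in a
documented order (axes, anchor points, SHG noise, TPEF noise), so equal
seeds give bit-identical volumes. Ground truth records the per-fiber axes,
the dominant-fiber axis per voxel (where the strongest fiber contribution
reaches the nominal-radius intensity), and any applied F. Macro scenes
render anti-aliased dark dots displaced by F about the marker centroid
(centre-of-mass of a rendered dot recovers truth to < 0.25 px); stress-
strain traces are piecewise-linear toe/linear curves, continuous at the
transition.

What the phantoms deliberately omit: fiber crimp and waviness, the dermal
basket-weave topology, fiber-fiber crosslink mechanics, depth-dependent
attenuation, and realistic SHG speckle. Passing tests therefore demonstrate
that the estimators recover known geometry and kinematics under controlled
conditions — orientation endpoints, strain transport, gate semantics — not
that they are unbiased on real dermal texture.

### Validation problem sizes

Unit tests run on 32–96-voxel cubes. The end-to-end strain recovery uses the
generator default geometry (128 × 128 × 64 voxels, 200 fibers, κ = 8,
noise σ = 2) warped by F = diag(1.095, 0.913, 0.960) plus 0.02 xy-shear; the
tracked tetrahedron recovers every Green-strain component within 0.01 and
det F within 3 %. The affine-oracle comparison uses 60 fibers of radius
1.6 µm in 192 × 192 × 96 voxels: windowed per-voxel orientation is only
identifiable where most windows see a single fiber, and at denser packing
(e.g. the 200-fiber default geometry) window mixing biases image-based DV
low by 0.05–0.11 — there even the ground-truth per-voxel axes disagree with
the per-fiber statistic, so the comparison would measure density, not the
warp machinery. For the same reason the oracle transports the ground-truth
*per-voxel* axes (the same voxel-weighted statistic the image estimator
targets) rather than the unweighted per-fiber axis list, whose finite-sample
DV differs by up to ~0.1 at κ = 0 with ~100 fibers.

## Known limitations

- The collagen segmenter is a threshold stand-in behind the CNN-shaped
  plug-in contract; absolute collagen fractions depend on the chosen method.
- The orientation estimator degrades where windows mix several differently
  oriented fibers (dense crossings); its DV is then biased toward the local
  mean orientation.
- Strain from a single tetrahedron inherits the error of its four vertices;
  no least-squares pooling over all tracked features is attempted.
- Incremental moduli treat each increment's equilibrium load as elastic;
  stress relaxation between increments is not modelled.
- No multiple-comparison correction is applied; tests mirror the analysis
  plan they implement.
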