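# Methods

This note documents the models, numerical choices and limitations of
`mtlmorph`, a pipeline for longitudinal morphometry of the medial temporal
lobe (MTL): volumetric atrophy rates, diffeomorphic (LDDMM) registration with
varifold surface matching, laminar thickness of the entorhinal/transentorhinal
cortex (ERC/TEC), subregional amygdala mapping against a high-field-style
atlas, and tau-PET SUVR quantification. Because the cohorts such analyses run
on are restricted-access, every stage is driven and validated by synthetic
phantoms with analytically known ground truth.

## Volumetry and atrophy rates

Structure volume is the voxel count of a label times the voxel size
(default spacing 1.0 x 1.0 x 1.2 mm, configurable). Each subject's
longitudinal volume trajectory gets an ordinary least-squares fit of volume
against age; the slope is the annualized rate of change in mm^3/yr, and the
percent rate divides by a baseline volume (x100). Two conventions for
"baseline" exist in practice; the default uses the regression-fitted value at
the first retained age, which is robust to noise in the first scan, with the
observed first volume available behind a flag. Negative slope means atrophy;
presentation-layer "atrophy rates" are the magnitudes of negative slopes.

Outlier scans are excluded before fitting: per region, the standard deviation
is computed across all observations in the cohort, and a timepoint is flagged
when its volume deviates from the subject's own mean by more than 2.5 of that
SD. The rule's two plausible readings (cohort-level vs within-subject SD) are
both implemented; the cohort-level SD is the default. A subject whose every
timepoint is flagged is unusable and reported as an error. ERC and TEC are
reported separately and as a merged ERC/TEC compartment; hemispheres are
distinct labels, pooled by averaging rates, never by summing volumes.

## LDDMM core

Deformations are geodesics of the point-particle LDDMM model: control points
`q_i` carry momenta `p_i` under the Hamiltonian
`H(q, p) = 1/2 sum_ij K(q_i, q_j) p_i . p_j` with a Gaussian kernel of width
`sigma_V` (mm). Any point is advected by the induced velocity field
`v(x, t) = sum_j K(x, q_j(t)) p_j(t)`; time is discretized by explicit Euler
with `T` steps (default 10; stages that only need short flows use 5). The
registration objective is

    E(p0) = lambda * sum_ij p0_i^T K(q_i, q_j) p0_j + D(phi . source, target)

where `D` is the squared varifold distance: surfaces are compared through
face centroids and area-weighted normals under a Gaussian spatial kernel
(width `sigma_W`) and the Binet orientation kernel `(n.m)^2 / (|n||m|)`,
which makes the metric invariant to the sign of face orientations. Labeled
structures enter as separate fidelity channels summed over structures, which
is what makes the multi-structure joint alignment possible.

Gradients are exact reverse-mode passes through the discrete forward
computation (hand-derived; no autodiff dependency) and are verified against
finite differences in the test suite. The default optimizer is L-BFGS-B on
the analytic gradient; a backtracking gradient-descent variant is selectable
(`optimizer="gd"`). Both record the accepted-energy trace, which is
non-increasing up to line-search tolerance. Inverse maps integrate the
velocity field backward in time with two Picard refinements per step; forward
composed with inverse stays within 0.1 mm on test grids. Jacobian
determinants are central differences of the forward map on a grid and are
positive for every accepted registration.

Kernel widths are geometric choices with no single correct value: structure-
scale alignment uses `sigma_V` comparable to the structure radius
(8-15 mm for whole-surface matching, 3-4 mm where spatially heterogeneous
deformation must be resolved, as in the subregion stage), and `sigma_W`
of 2-3 mm, about the voxel-to-feature scale. The trade-off weight `lambda`
defaults to 1e-3 (1e-2 where near-rigid solutions are expected); the
registration energy is dominated by fidelity, with the RKHS term preventing
momentum blow-up.

Label-image registration extracts per-label boundary surfaces by marching
cubes on a smoothed indicator (step size chosen to target ~2 mm mesh edges)
and registers them as varifold channels; control points are those boundary
vertices rather than a dense grid — at these problem sizes the boundary
carries all the information and conditions the optimization far better.
Label volumes are warped by nearest-neighbour pull-back through the inverse
map, so a deformed partition remains a partition exactly.

## Laminar thickness

The inner (white-matter-side) boundary is registered to the outer (pial)
boundary with the initial momentum constrained to the inner surface's
outward vertex normals: one scalar unknown per vertex, `p0_i = alpha_i n_i`.
This preserves the geodesic parametrization and gives an exact gradient
(`dE/dalpha_i = n_i . dE/dp0_i`). The alternative discretization — re-
projecting onto normals recomputed during optimization — coincides with this
one on the (near-)spherical geometries used for validation, where flows stay
radial by symmetry. Thickness is the polyline length of each vertex's
trajectory; vertices whose endpoints remain farther than 0.5 mm from the
outer surface are flagged unreliable and carry NaN, and a surface pair with
more than 20% flagged vertices should be treated as unusable (both
thresholds are package choices; the upstream exclusion they mirror — series
with vanishing thin compartments — has no published quantitative rule).

The scalar summary is the median of the vertex distribution, identical to
the 50% point of the empirical CDF (midpoint convention on ties); PMF/CDF
histograms default to the 1-5 mm range. Thickness atrophy rates follow the
same OLS-on-age convention as volumes, as percent of fitted baseline
thickness per year. On concentric spheres (r = 10, R = 12.5 mm, icosphere
subdivision 3) the median flow-line thickness is within 0.01% of 2.5 mm.

A population template of baseline outer surfaces is estimated by iterative
centroid averaging: start from the varifold-medoid surface, register the
template to each surface, move it by the mean endpoint displacement, and
repeat (cap 10 iterations, convergence at 0.05 mm mean displacement).
Thickness fields transport to the template by registering the template onto
each subject surface and pulling the value at the closest subject vertex;
flagged values propagate. Vertex-wise atrophy-rate maps are per-subject OLS
slopes on the common template, averaged within group.

## Amygdala subregion mapping

The atlas is a laterally tapered ("egg") ellipsoid partitioned into BMA,
BLA, CMA, LA and PA with the field-standard relative geometry (CMA
posterior-most, LA lateral-most, PA a medial sliver, BLA lateral to BMA).
The taper matters: a mirror-symmetric ellipsoid admits a 180-degree rotation
that registration cannot distinguish from the identity, which would let the
medial and lateral subregions swap.

Mapping is two-stage. First, all of a subject's timepoints are jointly
aligned to the first timepoint by multi-structure varifold LDDMM over the
amygdala, ERC, TEC and hippocampus boundaries; the subject midpoint template
is the atlas shot through the *average* of the per-timepoint initial momenta
(all registrations share the reference control points; the common-source
reading of "average initial momentum" is used). Second, the midpoint
template's whole-amygdala outline is registered to each timepoint and the
subregion labels ride through the map. Because labels are transported by a
single diffeomorphism, the subregions partition the deformed amygdala
exactly at every timepoint, and rates per subregion are ordinary volumetric
fits. The subregion stage uses `sigma_V = 3 mm`: wider kernels produce
near-affine maps that smear the medial-lateral contrast (and at 4 mm can
invert it on some geometries).

A particle route is also provided: boundary faces become particles (centroid
position, area-weighted normal, area weight, subregion label), and voxel
reconstruction assigns each voxel the label with the highest Gaussian-kernel
particle density (width: one voxel diagonal), with interior/exterior decided
by the nearest particle's normal sign and ties broken toward the smallest
label id.

The medial-shrinkage phantom contracts the transverse plane by a factor that
varies along the medial-lateral axis as a sigmoid crossing over at the LA
boundary (width 1 mm), so medial subregions shrink at the nominal medial
rate while LA is spared; ground-truth subregion volumes follow exactly from
the local Jacobian of this analytic map. PA is generated but small; headline
contrasts use BMA/BLA/CMA vs LA.

## PET SUVR

SUVR of an ROI is its mean tracer concentration divided by the mean over a
cerebellar gray-matter reference mask. The sum-over-voxels/volume form
reduces to the voxel-mean ratio on a uniform grid (the voxel-volume factors
cancel), which is how it is computed; SUVR is therefore invariant to global
intensity rescaling, and the reference region against itself scores exactly
1. PET and masks must share the MRI frame; a frame-of-reference check guards
against mismatched inputs. No partial-volume correction is applied.
Interhemispheric consistency is summarized as the signed distance of
(left, right) SUVR pairs from the line y = x, i.e. `(R - L)/sqrt(2)`.
SUVR-vs-atrophy association is OLS with a 95% confidence band for the mean
line (statsmodels), per structure and pooled across hemispheres.

## Synthetic cohort generator

The generator is the study-condition definition, not a tuning knob. Group
generative rates default to the control/MCI regimes of longitudinal 3T MTL
volumetry (ERC 2.90/4.03, amygdala 1.26/2.22, hippocampus 0.01/0.70 %/yr),
preserving the ERC ~ amygdala > hippocampus ordering. Percent-per-year
shrinkage is linear in volume by default — the estimand of the OLS fit —
with compounding behind a flag; shell thinning is geometric (ratio
`1 - r/100` per year), so thickness stays positive. Volume noise is
multiplicative log-normal parameterized by a coefficient of variation
(default 1%), standing in for segmentation jitter; structures get sub-voxel
random placement so rasterization error decorrelates across subjects.
Follow-up is 4 scans over 6 years (3 scans over 4 years in the fast demo
config), matching typical cohort designs. Between-subject rate spread has no
published anchor; it is fixed at SD 0.2 %/yr, deliberately modest so that
group means are identifiable at the cohort sizes used for validation — real
cohorts are substantially more heterogeneous, and recovery of *individual*
rates at realistic spread is not what the tests demonstrate.

What the phantoms do not emulate: scanner physics, MRI contrast, partial
volume effects, segmentation failure modes beyond multiplicative jitter,
non-ellipsoidal anatomy, or realistic between-structure correlation of
atrophy. Passing tests show the estimators recover known geometry and rates
under these idealized conditions; they do not certify performance on real
scans.

## Problem sizes and runtime

Validation runs at desk scale on one CPU: icosphere subdivision 3 (642
vertices / 1280 faces) for registration and thickness oracles, subdivision 2
for per-subject shells; subregion phantoms on ~1 mm grids with ~0.6 mm
atlases, meshes decimated to ~2 mm edges; cohorts of 20-50 subjects per
group for rate-recovery checks. The full demo pipeline (10 subjects, all
stages) completes in a few minutes; the two-stage subregion mapping is the
dominant cost (~45 s per subject).

## Known limitations

- Euler time-stepping is first-order; endpoint errors are O(1/T). The tests
  quantify this by step-refinement rather than assuming exactness.
- The varifold fidelity is correspondence-free, so recovered *pointwise*
  maps are only as identifiable as geometry allows; symmetric shapes can
  slide tangentially. Structure-scale kernels and the tapered atlas mitigate
  this, as described above.
- The thickness transport uses varifold registration plus closest-point
  pull-back rather than an elastic mesh-matching energy; on strongly folded
  real cortex this is a coarser approximation than on the shell phantoms.
- Template estimation averages endpoint displacements (a fixed-vertex-count
  centroid scheme); it does not re-mesh and inherits the initial medoid's
  topology.
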