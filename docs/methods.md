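# Methods

This note records the models, parameter defaults, numerical choices, and
limitations behind `elecloc`, in the order the pipeline runs.

## Coordinate conventions

Voxel indices are 0-based and affines map voxel *centers* to world mm in
RAS orientation. Two world frames are distinguished. *Scanner RAS* is the
frame of the NIfTI affine. *Surface RAS* is scanner RAS re-centered on
the geometric center of the imaged volume — the world coordinate of voxel
((n−1)/2, …) — which is the frame of surface meshes and electrode tables.
All synthetic fixtures use volume-centered affines so the two frames
coincide there, but the conversion is applied everywhere coordinates meet
a volume, and volumes carry an explicit frame tag so cross-frame
arithmetic fails loudly rather than silently.

Electrode tables default to zero-indexed channel numbering (matching
Python); the flag is persisted with the table and honored by montage
assembly and by manual label edits.

## Rigid CT→MRI registration

The similarity is normalized mutual information,
NMI = (H(A)+H(B))/H(A,B), over a joint histogram with **32 bins** per
axis. Intensities are clipped to the **1st–99th percentile** before
min–max binning: CT metal artifacts are orders of magnitude brighter
than bone and would otherwise compress the informative range into a few
bins. The joint histogram is Gaussian-smoothed with **σ = 1 bin** (a
Parzen-style regularizer) and renormalized so its total still equals the
number of overlapping samples.

Optimization is Powell's derivative-free method on −NMI over
(tx, ty, tz) in mm and intrinsic x–y–z Euler angles in degrees, rotation
taken about the fixed volume's center. Tolerances xtol = ftol = 1e-4,
at most 50 iterations per level. The pyramid runs factors **(4, 2, 1)**:
at each level both volumes are Gaussian-smoothed with σ = factor/2
voxels and the fixed grid is strided by the factor; coarse levels
subsample at most 200 000 fixed voxels (seeded), the finest level uses
the full grid. Each level warm-starts from the previous one, and the
per-level NMI and parameters are logged on the returned transform
(`level_log`), so the monotone shrinkage of the recovery error down the
pyramid is assertable.

One deliberate subtlety: the finest level is still smoothed with a
**0.5-voxel** Gaussian floor. Trilinear interpolation imprints a faint
lattice artifact on the NMI landscape whose local maxima can bias
sub-degree rotations; the half-voxel apodization removes it. On the
default phantom this took the worst-axis rotation error from ≈0.23° to
≈0.04° and made the per-level error sequence monotone.

If Powell fails to converge at any level the run returns the best
transform so far, flagged `converged = False` with a warning — the
observable failure mode of grossly wrong initial conditions, for which
the remedy is a rough manual pre-alignment passed as `init`.

Resampling the CT onto the MRI grid (`rCT`) is pull-based through the
inverse transform, trilinear by default, zero outside the field.

The maximum-intensity-projection slab used for electrode visualization
takes the per-pixel maximum over the current slice **±15 slices**
(clipped at the volume edge); a bright voxel 16 slices away is excluded.

## Grid interpolation and dural projection

Bilinear corner interpolation is exact for planar, uniformly spaced
grids and is the standard model for rigid high-density arrays; curved
grids are out of scope. The corner→channel convention is row-major
(corner 3 = channel (nrows−1)·ncols+1); a transposed convention is
exposed through the CLI flag `--corner-order`.

The grid frame takes the four directed edges of the corner
quadrilateral, forms each corner's normal as the normalized cross
product of its two adjacent edges, flips signs into a common half-space,
and averages. The mean normal's outward sign is set by pointing it away
from the pial centroid.

The dural envelope is the convex hull of the pial vertices, midpoint-
subdivided until no edge exceeds **3 mm**, then Taubin-smoothed
(**λ = 0.5, μ = −0.53, 30 iterations** by default) — the λ/μ pair gives
Laplacian smoothing without the volume shrinkage of the plain filter.
`smoothing_iters = 0` returns the subdivided hull unchanged, and the raw
hull is available for callers who want the exact hull of the worked
projection figure. An orbitofrontal variant builds the hull of the
vertex subset excluding a caller-supplied temporal-lobe label set, since
a whole-cortex hull bridges the Sylvian fissure under OFC coverage.

Projection casts a ray from each electrode along the mean normal and
takes the first Möller–Trumbore intersection (smallest non-negative t,
ties to the lowest triangle index). Because all electrodes move along
the same direction, transverse layout — and hence row-major neighbor
order — is preserved exactly, and pairwise distances can only grow.
Misses (possible for electrodes outside the hull pointing away) fall
back to the exact nearest point on the mesh (Ericson's region
classification) and are flagged per electrode rather than failing.
Strips and subtemporal electrodes are not auto-projected; projection is
opt-in per device.

## Anatomical labeling

Surface electrodes are labeled from their *projected* coordinates by the
annotation of the Euclidean-nearest pial vertex (k-d tree with explicit
lowest-index tie resolution, verified against an exhaustive scan). Depth
electrodes convert to scanner RAS, then to voxel indices rounded
half-away-from-zero, and take the LUT name of that voxel verbatim —
including white-matter labels; no nearest-gray fallback is applied, and
the caller is expected to review such rows. Id 0, unknown ids, and
out-of-volume coordinates yield "Unknown" (the last with a warning).
Label strings are copied verbatim from the annotation/LUT with no case
normalization, so cortical names are lowercase ("superiortemporal") and
volumetric ones keep LUT capitalization ("Left-Hippocampus").

Which atlas is used for surface vs depth labeling is entirely a property
of the annotation and parcellation resources passed in (conventionally a
coarse gyral atlas for surfaces and a finer one for depths); the code
imposes no atlas.

Montage assembly concatenates device coordinate blocks in montage order,
generates short ids as prefix+channel and long ids from a per-device
template, and refuses duplicate ids or count mismatches. Manual label
revisions ({name: [indices]}) touch exactly the listed rows, honor the
table's indexing base, commute when disjoint, and append to a provenance
log on the table.

## Warping to a template

Surface: snap to nearest subject pial vertex (snap distances reported;
>5 mm is flagged as the wrong-gyrus failure mode), carry to the paired
registered-sphere position, find the nearest template sphere vertex —
angular and chordal nearest coincide on the unit sphere, so the maximal
inner product is used, ties to the lowest index — and return that
template pial vertex. With subject == template the warp is exactly the
identity on snapped electrodes.

Depth: add the trilinearly interpolated displacement (mm) of a dense
field sampled on a voxel grid. Electrodes outside the field or its
validity mask pass through unchanged and are flagged. Computing either
the spherical registration or the volumetric warp is out of scope; both
are consumed as inputs and fabricated with exact ground truth by the
fixtures.

Warped coordinates are stored in a separate `elecmatrix_warped` block —
never overwriting native coordinates — so native/warped comparisons
remain possible. The QC report re-labels every electrode at its warped
position (template annotation for surface rows, template parcellation
for depths), lists mismatches first, and carries the overall agreement
fraction; a drop-list discards warped coordinates the reviewer rejects.

## Subcortical meshes

Per-structure binary masks are Gaussian pre-smoothed with **σ = 1
voxel** (σ = 0 gives the raw blocky isosurface used by the volume
oracles), padded by one voxel so structures touching the field of view
still close, triangulated by marching cubes at level 0.5, and mapped
through the affine into surface RAS. The default structure set is the 23
canonical subcortical structures with ids and colors from the standard
segmentation color lookup table, shipped as a CSV; left/right lateral
and inferior-lateral ventricles are kept as separate meshes.

## Synthetic fixtures

All generators are pure functions of (spec, seed) using the
counter-based Philox RNG, so outputs are byte-identical across runs and
platforms.

*Head phantom* (default 96³ voxels at 1 mm): T1 with nested gray/white
ellipsoids and a faint skull shell; CT with a bright skull shell
(2000 HU-like), faint soft tissue, and soft-edged spherical electrode
artifacts (radius 0.585 mm — half the 1.17 mm contact diameter of
high-density grids — with a ~1 mm bloom shoulder, peak 3200). Brain
semi-axes default to (33, 44, 38) mm: a distinctly anisotropic head, as
real heads are; near-equal axes would make one rotation nearly
unidentifiable by any intensity-based method. The displaced CT is
rendered analytically at rigidly transformed coordinates (no resampling
error), with the ground-truth transform — default (4, −3, 2) mm,
(3°, −2°, 1°) — and electrode centers returned. Additive Gaussian noise
σ = 2. Electrodes sit a few mm beneath the pial boundary so their
artifact centroids are not biased by skull intensity. Not emulated: bias
fields, partial-volume anatomy, beam hardening, gantry tilt.

*Pial surface*: an icosphere (default 3 subdivisions, 642 vertices,
radius 60 mm) radially perturbed by smooth random bumps and indentations
of peak amplitude 5 mm (gyri/sulci at caricature scale); the paired
sphere coordinates are the unperturbed unit icosphere, so the spherical
registration is exact by construction. Annotation: azimuthal sectors
named after gyral regions. Real sulcal geometry, cut medial walls, and
registration error are not emulated — passing tests show the warping
machinery is correct given a correct registration, not that spherical
registration itself is accurate.

*Parcellation*: one ellipsoidal blob per structure on a cubic lattice
spaced so blobs cannot overlap, ids per the standard LUT, blob centers
returned for oracle checks.

*Warp field*: per-component sinusoids with wavelength twice the field of
view (amplitude 3 mm default), sampled on the grid with the closed form
returned; trilinear interpolation error against the closed form is
bounded by A·(kh)²/8 ≈ 1 µm, far under the 0.01 mm oracle tolerance.

## Problem sizes and defaults in the tests

The registration suite uses the 96³ phantom (≈0.9 M voxels, ~30 s on one
CPU) and a 48³ half-scale phantom for self-registration and failure-mode
checks. The end-to-end pipeline test runs an 8×8 grid plus a 4-contact
depth on the same phantom. The acceptance script re-runs the full 96³
registration and every other headline computation from scratch in about
half a minute.

## Known limitations

- Registration assumes the initial misalignment is within the capture
  range of the pyramid (tens of mm / ~10–20°); beyond that it returns a
  flagged non-convergent result rather than recovering.
- Bilinear grid interpolation cannot represent grids curved around
  cortex; the projection step absorbs mild curvature only.
- Depth labels are the verbatim voxel label; electrodes in white matter
  get white-matter labels.
- The dural envelope is a smoothed convex hull: adequate for lateral
  grids, crude for inferior/medial surfaces (the OFC submesh variant
  mitigates one such case).
- QC renders are static 2D projections, by design; no interactive 3D
  viewer is included.
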