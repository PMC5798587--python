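# Methods

## Coordinate and unit conventions

Volumes are indexed `[x, y, z]`; slice *k* of a TIFF stack maps to
increasing z. Voxel indices are 0-based and physical coordinates follow
the voxel-center convention: the coordinate of voxel (i, j, k) is
`origin + voxel_size · (i, j, k)` with isotropic `voxel_size` in μm.
After alignment, +z points from the metaphyseal shaft toward the joint
surface. The FE module works in mm-MPa-N: voxel sizes are converted from
μm to mm at meshing so that Young's moduli in MPa and loads of order 1 N
need no further scaling.

## Denoising

Tomographic shot noise is removed by a 3D median filter. The `kernel`
parameter is a half-width: the window is (2·kernel − 1)³ voxels, so the
default `kernel = 2` means a 3×3×3 median — the smallest odd window
consistent with a "small" kernel. Even-sided median windows are
ill-defined, so this interpretation is a deliberate package choice and is
surfaced here prominently. On sparse binary impulse noise (occupancy
≲ 0.2), repeated application reaches a fixed point within a few
iterations; dense random binary fields can oscillate indefinitely under a
3×3×3 median, which is why the idempotence property is only claimed, and
tested, in the impulse-noise regime the filter exists for.

## Alignment

Instead of an interactive manual alignment, the package accepts an
explicit rigid transform or an `"auto"` mode that rotates the principal
axis of the mineralized mask onto +z (Rodrigues rotation). Grayscale
volumes are resampled trilinearly; label volumes use nearest-neighbor so
labels are never blended. Near-spherical masks (top two principal
variances within 5% of each other) are rejected with a request for an
explicit alignment rather than guessing.

## Segmentation and compartment labeling

Mineralized tissue is segmented by seed-based region growing: the result
is exactly the union of connected components of the thresholded set
`lo ≤ gray ≤ hi` that contain a seed. Connectivity defaults to 26
(faces + edges + corners) because bridges are thin oblique structures
that face-connectivity would fragment; 6-connectivity is available.

The growth-plate band is located automatically as the z-interval of
minimal mineralized cross-sectional area: the per-slice area profile is
smoothed with a 5-slice moving average, the interior argmin is taken, and
the band is expanded over contiguous slices whose raw area stays below
`min + 0.1 · (peak − min)`, where `peak` is the smaller flanking maximum.
A band is only accepted if the minimum is at most half the flanking peak;
otherwise (monotone or solid profiles) an explicit `gp_band_hint` is
required. Thin bridges crossing the gap occupy far less than 10% of a
plate cross-section and so do not close the band.

Labels partition the volume into background, epiphysis (mineralized,
above the band), metaphysis (mineralized, below), growth-plate cartilage
(non-mineralized, inside the band), and bridge candidates (mineralized,
inside the band). Keeping in-band mineral as its own label lets the FE
module assign it bone material, without which a bridge would be modeled
as cartilage.

When automatic parameters are requested, the tolerance lower bound is the
midpoint between the cartilage and bone class means estimated from a
3-class Otsu partition; with the phantom's guaranteed ≥ 4σ class
separation this puts the threshold ≥ 6σ from both means, making
mis-thresholding of any voxel overwhelmingly unlikely. One seed is
placed at the brightest voxel of each z-half so both plates are seeded
even when no bridge connects them.

## Bridge detection and morphometry

A candidate bridge is a connected component of mineralized voxels
restricted to the band that is adjacent — under the chosen connectivity —
to both the epiphysis and the metaphysis ("crossing the entire growth
plate width" made topological and automatic; a click-list mode restricts
detection to user-identified components). Spurs touching one side only
are excluded. Ids are deterministic, ordered by the (min z, min y, min x)
bounding-box corner.

Components smaller than `min_voxels` (default 125) are discarded; the
boundary semantics are "smaller than are removed", so a 125-voxel
component survives.

The center of each bridge is a skeleton point: the package computes the
Euclidean distance-transform medial axis — voxels whose boundary distance
is maximal within their 26-neighborhood, with a half-voxel plateau
tolerance absorbing rasterization jitter — and selects the medial voxel
nearest the component centroid (ties broken by smallest (z, y, x)). A
sub-voxel refinement averages the adjacent medial voxels and is accepted
only if the refined point still lies inside the component, preserving the
guarantee that centers of bent bridges stay inside the mineralized
tissue, where a raw centroid may not. Iterative-thinning skeletons were
rejected because they collapse short thick cylinders to a point near one
end. Single-voxel components fall back to that voxel (logged).

## Projection and areal number density

Bridge centers travel along straight +z lines onto the joint surface,
defined per (x, y) column as the topmost mineralized voxel over the
plateau footprint (columns containing at least one epiphyseal voxel).
Heights at non-integer positions use bilinear interpolation over the
defined neighbor columns with renormalized weights; a center whose column
has no defined neighbor is reported as `missed`, never silently dropped,
and excluded from density.

N_A is the count of projected points per square window (default
256 μm side). Windows are half-open tiles `[x0+m·w, x0+(m+1)·w) ×
[y0+n·w, y0+(n+1)·w)` so each point is counted exactly once and
Σ counts = number of projected points on every run. The grid anchors at
the minimum (x, y) corner of the footprint bounding box — the anchor is
not anatomically defined, so a deterministic convention is used and
recorded in provenance. Overlapping-window variants are not offered.
The overlay is written as a PNG heat map (one pixel per surface column,
viridis colormap, Pillow output with no timestamps — byte-deterministic)
and an ASCII PLY surface mesh with per-vertex density colors.

## Synthetic phantoms

A phantom is two solid mineralized plates separated by a cartilage gap,
crossed by disk-swept cylindrical bridges (optional shear tilt up to 30°,
exercising 26-connectivity), with an optional sinusoidal undulation of
the top (joint) surface and Gaussian noise around per-tissue gray means
(defaults 200/80/20, σ = 10, 5 μm voxels — a benchtop-scanner-like
contrast with ≥ 4σ separation so segmentation is well-posed by
construction). Bridges extend one voxel into each plate to guarantee
spanning; ground-truth bridge volumes count in-band voxels only, which is
what the detection chain measures. Bridge overlap or contact (within the
26-neighborhood) is rejected with the offending pair named. The
gray-level model deliberately omits beam hardening, ring artifacts and
partial-volume blur: the analysis pipeline, not scanner physics, is under
test, so passing phantom tests demonstrates algorithmic correctness, not
robustness to every scanner artifact.

`sweep_bridge_volumes` places isolated spanning components of exactly
requested integer voxel counts by direct voxel placement: a one-voxel
column through the gap, grown nearest-first (ordered by squared xy
distance, then z, y, x — an order that keeps the set connected) until the
in-band count matches. Requests below the gap thickness are impossible
(such a component cannot span) and are rejected.

The randomized layout generator places bridges on a jittered coarse grid
with pitch chosen so components cannot touch even at maximal radius and
tilt; 128³ layouts with k ∈ {0, 1, 5, 12} bridges are the standard
recovery suite (10 seeded layouts each), sized to keep the whole suite in
tens of seconds.

## Finite elements

Labeled voxels are optionally binned by majority vote (ties to the
smaller label) and decomposed into 5 tetrahedra per voxel with
mirror-alternating orientation by voxel parity, so shared faces conform
across neighbors; summed element volume equals retained voxel volume
exactly. Materials are isotropic linear elastic, defaulting to bone
E = 17,000 MPa, ν = 0.3 (epiphysis, metaphysis, bridges) and growth-plate
cartilage E = 6 MPa, ν = 0.49.

The stiffness of the constant-strain tetrahedron is V·BᵀDB; the global
system is solved with a sparse direct factorization after eliminating
constrained dofs (zero or prescribed displacements). Before solving, the
six rigid-body modes are checked against the constraint set by a rank
test, and an unconstrained mode is reported by name. Reactions are
recovered as K·u − f on constrained dofs; equilibrium (Σ reactions +
Σ loads = 0 per component) holds to the solver residual, bounded at
1e-8·‖f‖ in the test contract.

The default load case emulates static compression of the tibia: all
bottom (min-z) nodes fixed vertically; three pins remove the in-plane
rigid modes — the fully fixed pin at the lexicographic min-(x, y) bottom
node, the x-restraint at the max-y node and the y-restraint at the max-x
node. The x-restraint must sit at a different y than the fully fixed pin
(and symmetrically for y), otherwise rotation about z remains free; the
rank check enforces this. The total force (default 1 N ≈ three times
mouse body weight, downward) is split equally between the medial and
lateral halves of the top surface, uniformly per node; an area-consistent
(tributary) load builder is also provided and is the right choice when
comparing against uniform-stress closed forms, which it reproduces to
round-off.

Mesh sensitivity follows the 5% rule: the asymptote is estimated as the
finest-mesh metric and the chosen mesh is the coarsest whose metric
deviates at most 5% from it; the full convergence table is returned. Any
scalar metric series may be supplied (the demonstration uses mean axial
stress in the growth-plate band).

## Numerical and determinism notes

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configs give byte-identical CSV
  and PNG artifacts.
- Region growing, component labeling and filtering are exact set
  operations — no tolerance parameters beyond the gray interval.
- The near-incompressible cartilage (ν = 0.49) is handled by the direct
  solver without locking countermeasures; TET4 elements do lock
  volumetrically, so absolute cartilage stresses are approximate at
  coarse resolution while the bridge/cartilage stress contrast (the
  quantity of interest, orders of magnitude) is robust.
- Problem sizes in tests (128³ recovery phantoms, ≤ ~60k-element FE
  solves) were chosen to keep the full suite around half a minute while
  leaving every assertion at its stated tolerance.

## Known limitations

- No tomographic reconstruction, flat-field or ring-artifact handling;
  volumes are assumed reconstructed.
- Projection is along +z only; no surface-normal option.
- No statistical comparison of density maps across groups.
- FE is linear static; no contact, poroelasticity, viscoelasticity or
  growth simulation.
- Medial/lateral load regions are split at the median x of the top
  surface — a convention, not anatomy.
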