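# physis

3D quantification of epiphyseal growth-plate bridging from microCT
volumes, with image-based linear-elastic finite-element analysis of the
loaded tibia.

## The problem

The growth plate (physis) is the cartilaginous region near the ends of
long bones where longitudinal growth occurs. As growth ceases, mineralized
**bony bridges** form across the plate, eventually fusing epiphysis to
metaphysis. Because the cartilage is non-mineralized it appears as a
low-intensity band in microCT, and bridges appear as mineralized columns
crossing it. This package provides, for skeletal biologists working with
benchtop or synchrotron microCT of small-animal bones:

1. **Bridge morphometry** — seed-based region growing of mineralized
   tissue, automatic location of the growth-plate band, detection of
   connected mineralized components that span the band (touching both the
   epiphyseal and metaphyseal bone), a minimum-volume filter (default
   **125 voxels**, suppressing partial-volume artifacts), and one center
   point per bridge from its medial-axis skeleton.
2. **Areal number density maps** — bridge centers are projected along
   straight +z lines onto the tibial joint surface, and the areal number
   density *N*<sub>A</sub> is counted per **256 μm × 256 μm** window,
   rendered as a heat map and as a colored 3D surface overlay.
3. **Finite elements** — labeled voxels become conforming linear
   tetrahedral meshes (5 tets/voxel, parity-alternating); static
   compression (~1 N total, split between medial and lateral joint
   regions) is solved with isotropic linear elasticity (bone
   *E* = 17,000 MPa, ν = 0.3; growth plate *E* = 6 MPa, ν = 0.49) and
   post-processed to von Mises stress
   σ<sub>vm</sub> = √(½[(σ₁₁−σ₂₂)² + (σ₂₂−σ₃₃)² + (σ₃₃−σ₁₁)²] + 3(σ₁₂²+σ₂₃²+σ₃₁²)).
4. **Synthetic phantoms** — two mineralized plates separated by a
   cartilage gap crossed by configurable bridges, with exact voxel-level
   ground truth, so every pipeline stage is testable without a scan.

## Worked example

`examples/quantify_bridges.py` builds a noisy 128³ phantom with five known
bridges and runs the full chain:

```
growth-plate band located at z = (12, 21) (constructed at (12, 21))
5 spanning components, 5 after the >=125 voxel filter (true count: 5)
  bridge 1: 290 voxels (36250 um^3), center [150. 150.  80.] um
  bridge 2: 370 voxels (46250 um^3), center [450. 150.  80.] um
  ...
projected 5 bridges onto the plateau; N_A per 256 um window:
[[1 1 0]
 [1 2 0]
 [0 0 0]]
```

The band was located automatically from the minimum of the mineralized
cross-section profile; every detected voxel count equals the generator's
ground truth; the window grid shows two bridges falling in the same
256 μm tile (*N*<sub>A</sub> = 2) and one empty corner of the plateau.

`examples/fe_stress_concentration.py` meshes a single-bridge phantom and
solves the 1 N compression case:

```
mesh: 40320 TET4 elements, 9375 nodes
equilibrium residual: 8.85e-13
peak von Mises inside the bridge: 4937.3 MPa
median von Mises in the cartilage: 3.51 MPa
concentration ratio: 1406x
```

The stiff mineralized column carries essentially the whole load across
the compliant cartilage — the mechanical signature of growth-plate
bridging acting as a stress concentrator.

## Command line

```bash
physis phantom --spec spec.toml --out vol.nrrd --truth truth.json
physis segment --input vol.nrrd --out labels.nrrd
physis bridges --labels labels.nrrd --out bridges.csv
physis density --labels labels.nrrd --bridges bridges.csv --out overlay
physis fem     --labels labels.nrrd --out result.vtk
physis all     --config run.toml
```

Exit codes: 0 success, 2 validation error, 3 stage failure. Every run of
`physis all` writes a `provenance.json` with all effective parameters.

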