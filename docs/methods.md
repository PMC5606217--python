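# Methods

## Skeleton model

A morphology is a forest of *sections* (maximal non-bifurcating runs of
samples) rooted at a soma. A sample is a 3-D position (μm) with the local
cross-section radius (μm); consecutive samples form *segments*. A child
section's first sample is the shared bifurcation sample of its parent, so
per-section segment emission enumerates each tree edge exactly once.
Soma samples (SWC type 1) are collapsed to centroid + mean radius; three
or more are additionally kept as an ordered planar contour (the reader
option `soma_profile="never"` discards it, for files where a multi-sample
soma is not a contour). Structure codes outside {1,2,3,4} map to *other*
and are treated as dendrites downstream. Coordinates are used as found in
the file; no unit inference.

## Artifact repair

Order is fixed: disconnected → overlap marking → internal-sample removal.

* **Disconnected starts.** The soma *extent radius* is the distance to
  the farthest contour point, falling back to the mean radius. Any
  first-order start beyond the extent (with a 1e-9 relative tolerance so
  starts sitting exactly on the extent are left alone) is moved to the
  extent distance along its original direction from the centroid — the
  repair preserves direction exactly, so a start at 20 μm with a farthest
  contour point at 10 μm lands at exactly 10 μm.
* **Overlap.** Two first-order sections overlap when the angle between
  their start directions is below the sum of their angular radii
  (`asin(min(1, r/d))` — the half-angle of the spherical footprint their
  cross-section projects onto the soma). Within each connected component
  of this overlap graph the section with the largest start radius is
  *primary* (ties: lowest index); the others are demoted — excluded from
  soma growth but still meshed, with the conic centroid joint providing
  continuity.
* **Internal samples.** First-order samples closer to the centroid than
  the *mean* radius (deliberately conservative: the extent radius could
  amputate valid proximal dendrite) are deleted; a section left with
  fewer than two samples is dropped with its subtree and reported.

Repair never changes radii, adds samples, or touches order ≥ 2 sections;
the report (relocations, demotions, removals) replays to the repaired
skeleton. The chain is idempotent whenever post-removal section heads lie
within the soma extent — true for all generated fixtures, whose neurites
start on the soma sphere; a pathological head beyond the extent would be
clamped only on a second pass.

## Soma reconstruction

The soma grows from a geodesic icosphere (subdivision 4 → 2562 vertices,
even spacing; radius = minimal centroid-to-first-sample distance over
primary sections, mean radius if there are none). Each primary section's
initial cross-section is spherically projected onto the sphere; the
captured vertices are flattened onto the projected cap's circle —
re-spaced uniformly in azimuth while keeping their cyclic order, so the
ring's vertex centroid coincides with its geometric center and the
triangulation is untouched — and registered as a rigid *hook*. A
footprint capturing no vertex raises an error naming the cure (finer
subdivision). Over K = 100 pull steps each hook ring is kinematically
interpolated in position and radius from the sphere to the section's
first sample; hook progress toward the target is monotone by
construction. Between steps the free vertices relax to quasi-static
equilibrium: linear springs on the icosphere edges (stiffness 1, rest
length = initial length, unit mass) plus a weak pressure term
(weight 0.1) pushing the enclosed volume back toward its initial value so
the membrane cannot collapse between distant hooks. Relaxation is
heavy-ball explicit integration — `v ← 0.85·(v + 0.6·F)`, `x ← x + 0.6·v`
— until the residual force drops below 1e-3 (μm with unit stiffness),
capped at 400 iterations per step; exceeding the cap raises an error
rather than returning a non-equilibrium shape. The step size and momentum
were chosen for fast settling on μm-scale somata (the residual threshold
is absolute, so very large somata converge more slowly). The simulation
never edits topology, hence watertightness is preserved at every step,
and the final ring sits exactly on its target (tolerances tol_pos
= 0.1 μm, tol_rad = 5 % are checked, not enforced by snapping). The
whole simulation is deterministic; no randomness is involved.

## Neurite meshing

Branch decomposition walks each neurite with a stack: at a bifurcation
the child whose first distinct sample has the largest radius continues
the current branch (ties: lowest child index); the siblings are stacked
and later seed their own branches. Every section lands in exactly one
branch and the branch count equals the terminal-section count. Each
branch is swept into a closed tube: an n-gon ring (default 16 sides) of
the local radius at every sample, rings joined by quad pairs, ends capped
with triangle fans. Ring frames are propagated by parallel transport
(rotation-minimizing), avoiding twist at high curvature; coincident
consecutive samples are dropped. Root branches are prepended a conic
segment from the soma centroid with ring radius 1.5× the first sample
radius — invisible for primary branches, essential for demoted ones.
Straight two-sample branches reproduce the analytic n-gon prism volume
`L·(n/2)·r²·sin(2π/n)` to machine precision. Meshing is linear in the
section count (local information only). Per-type maximum branching
orders (axon/dendrite) prune sections before decomposition. Components
are allowed to interpenetrate: the volumetric union downstream is what
must be faithful, not any single surface.

The watertightness validator counts boundary edges (face incidence 1),
non-manifold edges (incidence ≥ 3) and non-manifold vertices (incident
faces not forming a single fan when glued across manifold edges, or
touching a non-manifold edge). Every emitted component must report
(0, 0, 0).

## Voxelization

The grid spans the union AABB of all transformed components; the largest
axis is split into `resolution` voxels (spacing isotropic) and a
one-voxel empty margin is added on every side so border flood seeds are
always exterior. Occupancy is bit-packed LSB-first, flat index
`i + nx·(j + ny·k)`; payload is `ceil(n/8)` bytes with a 2 GiB default
cap.

Surface voxelization sets a bit iff the voxel box overlaps a triangle,
via the standard 13-axis separating-axis test (the 3 box axes are handled
by candidate enumeration over the triangle's index AABB). Candidate
ranges are widened by 1e-6 voxel and the box half-size by a 1e-9 relative
hair so a face lying exactly on a voxel boundary conservatively claims
both neighbours instead of falling between them to rounding. Writes are
idempotent bitwise-OR scatters; multi-worker runs rasterize disjoint
component subsets into private payloads OR-reduced at the end, so results
are independent of worker count and component order.

Solid voxelization flood-fills the exterior of each z-slice independently
from its border with 4-connectivity and inverts: 4-connected fill cannot
leak diagonally through the 8-connected conservative shell of a closed
component, so the result is interior ∪ shell exactly; every voxel whose
center lies inside a watertight component is set. Components failing the
watertightness check are a hard error. Two caveats are inherent to the
approach and documented by tests:

* **Conservative dilation.** The solid contains every voxel box touching
  the surface, i.e. the shape dilated by about half a voxel. For a
  radius-20-voxel sphere this adds ≈ +11 % to the voxel count over
  (4/3)πr³ (Steiner: ≥ 4πr²·(1/2 voxel) ≈ +7.5 % from the surface term
  alone); the relative excess decays as 1/r and is negligible at
  circuit-scale resolutions. Away from this one-voxel boundary band the
  classification is exact: non-shell voxels match ray-crossing-parity
  classification of their centers on all toy fixtures.
* **Slice-enclosed pockets.** Exterior regions enclosed within every
  individual slice — the hole of a torus whose axis is the slicing
  axis — are claimed by the per-slice fill. Neuronal geometry does not
  produce such pockets along a fixed axis in practice; the toy-mesh
  oracle fixtures orient the torus axis perpendicular to z, as any
  slice-based method requires.

## Annotation and brightfield projection

Labels are uint16 (0 = extracellular) stored beside, not inside, the
1-bit occupancy; where neurons overlap the last-listed label wins. Each
label maps to optical properties: an absorption spectrum μa(λ) in 1/μm
(scattering and anisotropy fields exist for future fluorescence /
optogenetics work but are ignored here). The projector is orthographic
and absorption-only: per pixel `T(λ) = exp(−Σ_ray μa(label,λ)·spacing)`,
composited over a coarse Xenon-lamp spectrum (380–720 nm, illustrative
not metrological) with Gaussian RGB colour-matching bands at 600/550/450
nm, normalized so empty pixels are white. The built-in "golgi_stain"
absorber is a flat 0.05 /μm placeholder — real Golgi coefficients are not
tabulated anywhere we know of — and fully configurable. A focal stack
partitions the volume into slabs along the projection axis; image *i*
adds the optical density of slab *i* sharp and every other slab blurred
by a Gaussian of σ = 2 px × slab distance (configurable), a visual
defocus emulation, not an optics model.

## Synthetic fixtures

The generator emulates digitized multipolar cells: a 5 μm soma,
3 neurites starting on the soma sphere with pairwise-separated
directions, sections as 4-segment random walks (5 μm mean step, ±30 %
length jitter, 0.3 direction noise), branching with probability 0.7 up
to order 3, child radii tapered ×0.8 with one child randomly thicker
(×1 vs ×0.7) so the largest-radius decomposition is non-trivial; primary
dendrite radius is 0.25× the soma radius, keeping hook footprints well
above the icosphere vertex spacing. Randomness comes only from numpy's
counter-based Philox generator, so fixtures are bit-identical across
platforms per seed. Artifact injection moves a first-order start to 2.5×
the soma radius (disconnected), rigidly rotates one neurite into
another's footprint (overlapping), or prepends samples at 0.4/0.7× the
soma radius (internal). What the fixtures do *not* model: realistic
morphometry distributions, spines, somatic contours from imaging, or
tracing noise along the branch; green tests demonstrate geometric and
topological correctness of the pipeline, not biological fidelity of
inputs.

## Problem sizes and determinism

Default study conditions: icosphere subdivision 4, K = 100 pull steps,
16-sided tubes, fixture populations of 20 neurons, voxel grids of
40–160 resolution in tests (the acceptance script uses 62–128), all on
one CPU in about a minute. Every stage is deterministic: identical
inputs, configuration and seeds give byte-identical SWC, PLY and volume
payloads regardless of worker count.
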