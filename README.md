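# morphovox

Turn digitized neuron skeletons into watertight surface meshes, solid
voxel volumes and simulated brightfield micrographs.

Digitally reconstructed neurons are distributed as SWC skeletons: trees of
3-D sample points with a cross-section radius, rooted at a soma described
only by a centroid, a mean radius and sometimes a planar contour.
Volumetric studies of cortical tissue — simulating how a stained slice
looks under a transmitted-light microscope, for instance — need solid
occupancy volumes instead, and solid voxelizers require closed two-manifold
("watertight") surfaces that are notoriously hard to build from noisy
tracings. `morphovox` implements a pipeline for computational
neuroscientists that side-steps the single-watertight-mesh problem:

1. **Repair** the three classic soma-adjacent artifacts: first-order
   branches disconnected from the soma (their start sample is pulled back
   to the soma extent along its original direction), overlapping
   first-order branches (only the thickest of each overlapping cluster
   drives soma growth), and branch samples lying inside the soma (removed).
2. **Mesh piecewise-watertight**: one closed component per structure
   instead of one impossible global mesh. The soma is grown from an
   icosphere by a mass–spring soft-body simulation whose rigid "hook"
   rings are pulled onto the first-order branch cross-sections; each
   neurite is partitioned into branches by largest-radius continuation and
   swept into a closed tube (n-gon cross-sections, parallel-transport
   frames, fan caps, a conic joint to the soma centroid). Components may
   interpenetrate — each is individually watertight, which is all the
   voxelizer needs.
3. **Voxelize solid**: union bounding box → bit-packed grid (1 bit/voxel)
   → conservative surface rasterization (13-axis separating-axis
   triangle/box test) → per-slice 2-D flood fill of the exterior and
   inversion. Per-pixel transmission follows Beer–Lambert,
   `T(λ) = exp(−Σ μa(label, λ)·Δs)`, for the brightfield projector.
4. **Annotate & project**: per-neuron labels with optical properties
   (e.g. a Golgi-stain absorber) and an orthographic absorption-only
   brightfield image or focal stack.

A deterministic synthetic-morphology generator (counter-based PRNG, with
injectable artifacts) makes the whole pipeline testable without any data
download.

## Worked example

```sh
python examples/02_mesh_neuron.py
```

```
10 watertight components:
  soma                   soma     5120 faces  defects (nm edges, nm verts, boundary) = (0, 0, 0)
  neurite_0_branch_0     neurite   448 faces  defects (nm edges, nm verts, boundary) = (0, 0, 0)
  ...
  neurite_2_branch_2     neurite   160 faces  defects (nm edges, nm verts, boundary) = (0, 0, 0)
```

One component per branch plus the soma; `(0, 0, 0)` means zero
non-manifold edges, zero non-manifold vertices and zero boundary edges —
each component is a closed two-manifold surface. Voxelizing a two-neuron
circuit (`examples/03_voxelize_circuit.py`) prints

```
grid (162, 85, 110) at 0.971 um/voxel
payload 189338 bytes for 1514700 voxels (1.000 bits/voxel)
occupied voxels: 7007 (0.463% of the grid)
```

i.e. the occupancy grid really costs one bit per voxel, and the two cells
fill ~0.5 % of their bounding volume. The brightfield example
(`examples/04_brightfield.py`) reports transmissions in `[0.58, 1.0]`:
the darkest pixel corresponds to ~11 μm of stained path at
μa = 0.05 /μm.

The same stages are scriptable from the shell:

```sh
morphovox fixtures --out fx --count 5 --seed 1 --artifacts
morphovox pipeline fx/neuron_001.swc --out out --resolution 256
```

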