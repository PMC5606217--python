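"""Branch decomposition and swept-tube meshing of neurites.

A neurite tree is first partitioned into *branches*: linear concatenations
of sections chosen by largest-radius continuation.  Starting at the
first-order section, the child with the thickest first cross-section
continues the current branch at every bifurcation while its siblings are
parked on a stack; each parked section later seeds a new branch.  Branches
therefore end at terminal sections, and the number of branches equals the
number of terminal sections.

Each branch is then swept into a closed tube: an n-gon cross-section of
the local sample radius at every control point, rings joined by quad pairs
and the two ends capped with triangle fans.  Cross-section frames are
propagated by parallel transport (rotation-minimizing), which avoids the
tube twisting at high curvature.  The branch that starts a neurite is
additionally connected to the soma centroid by a conic segment so that
branches excluded from soma growth still join the cell body volume.

Every emitted component is individually watertight; components are allowed
to interpenetrate — the volumetric union downstream makes the overlap
harmless.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .errors import DegenerateSegment, InvalidSides
from .morphology import MorphSample, Morphology, Section, Structure
from .soma import SomaConfig, build_soma
from .validate import WatertightReport, validate_watertight

__all__ = [
    "Branch",
    "MeshConfig",
    "PiecewiseMesh",
    "decompose_branches",
    "sweep_branch",
    "mesh_neuron",
]


@dataclass
class Branch:
    """A linear run of samples spanning one or more sections."""

    samples: list[MorphSample]
    is_root_branch: bool
    source_sections: list[int] = field(default_factory=list)

    @property
    def structure(self) -> Structure:
        return self.samples[-1].structure


@dataclass
class MeshConfig:
    """Tessellation and scope controls for neuron meshing.

    ``sides``: number of tube cross-section sides.  ``root_taper``: radius
    of the conic soma connection at the centroid, as a multiple of the
    branch's first sample radius.  ``max_axon_order`` / ``max_dendrite_order``:
    branching orders beyond these are dropped before decomposition
    (``None`` keeps everything).  ``soma``: numerics forwarded to the soma
    builder.
    """

    sides: int = 16
    root_taper: float = 1.5
    max_axon_order: Optional[int] = None
    max_dendrite_order: Optional[int] = None
    soma: SomaConfig = field(default_factory=SomaConfig)


@dataclass
class PiecewiseMesh:
    """Named set of overlapping, individually watertight components."""

    components: list[tuple[str, str, trimesh.Trimesh]] = field(default_factory=list)

    def add(self, name: str, role: str, mesh: trimesh.Trimesh) -> None:
        assert role in ("soma", "neurite")
        self.components.append((name, role, mesh))

    def validate(self) -> dict[str, WatertightReport]:
        return {name: validate_watertight(mesh) for name, _, mesh in self.components}

    def meshes(self) -> list[trimesh.Trimesh]:
        return [mesh for _, _, mesh in self.components]


def _index_sections(neurite: Section) -> dict[int, int]:
    return {id(sec): k for k, sec in enumerate(neurite.walk())}


def decompose_branches(neurite: Section) -> list[Branch]:
    """Partition a neurite's sections into branches by largest-radius
    continuation (ties break by lowest child index)."""
    index = _index_sections(neurite)
    branches: list[Branch] = []
    stack: list[Section] = [neurite]
    while stack:
        start = stack.pop()
        samples = list(start.samples)
        sections = [index[id(start)]]
        cur = start
        while cur.children:
            # the shared head sample is identical across siblings; compare
            # the first sample past the bifurcation
            best = max(
                range(len(cur.children)),
                key=lambda c: (cur.children[c].samples[1].radius, -c),
            )
            for c, child in enumerate(cur.children):
                if c != best:
                    stack.append(child)
            cur = cur.children[best]
            samples.extend(cur.samples[1:])
            sections.append(index[id(cur)])
        branches.append(
            Branch(
                samples=samples,
                is_root_branch=start is neurite,
                source_sections=sections,
            )
        )
    return branches


def _parallel_transport_frames(tangents: np.ndarray) -> np.ndarray:
    """Rotation-minimizing frames: returns (n, 2, 3) orthonormal pairs
    perpendicular to each tangent."""
    n = len(tangents)
    frames = np.empty((n, 2, 3))
    t0 = tangents[0]
    a = np.array([1.0, 0.0, 0.0])
    if abs(t0 @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t0, a)
    e1 /= np.linalg.norm(e1)
    frames[0] = (e1, np.cross(t0, e1))
    for k in range(1, n):
        prev_t, cur_t = tangents[k - 1], tangents[k]
        axis = np.cross(prev_t, cur_t)
        s = np.linalg.norm(axis)
        c = float(np.clip(prev_t @ cur_t, -1.0, 1.0))
        e1 = frames[k - 1, 0]
        if s > 1e-12:
            axis = axis / s
            # Rodrigues rotation taking prev_t onto cur_t
            e1 = (
                e1 * c
                + np.cross(axis, e1) * s
                + axis * (axis @ e1) * (1.0 - c)
            )
        elif c < 0:  # 180° reversal: keep e1, flip handedness via e2
            pass
        e1 = e1 - (e1 @ cur_t) * cur_t
        e1 /= np.linalg.norm(e1)
        frames[k] = (e1, np.cross(cur_t, e1))
    return frames


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    segs = points[1:] - points[:-1]
    segs = segs / np.linalg.norm(segs, axis=1)[:, None]
    tangents = np.empty_like(points)
    tangents[0] = segs[0]
    tangents[-1] = segs[-1]
    if len(points) > 2:
        mids = segs[:-1] + segs[1:]
        norms = np.linalg.norm(mids, axis=1)
        # opposing segments: fall back to the incoming direction
        bad = norms < 1e-12
        mids[bad] = segs[:-1][bad]
        norms[bad] = 1.0
        tangents[1:-1] = mids / norms[:, None]
    return tangents


def sweep_branch(
    branch: Branch,
    sides: int = 16,
    soma_centroid: Optional[np.ndarray] = None,
    root_taper: float = 1.5,
) -> trimesh.Trimesh:
    """Sweep a branch poly-line into a closed tube.

    Rings of ``sides`` vertices are placed at every sample with the local
    radius, consecutive rings are stitched with quad pairs, and both ends
    are capped with triangle fans.  Coincident consecutive samples are
    dropped.  For a root branch a conic segment from ``soma_centroid``
    (ring radius ``root_taper`` × first sample radius) is prepended.
    """
    if sides < 3:
        raise InvalidSides(f"sides must be >= 3, got {sides}")
    pts = [branch.samples[0].position]
    radii = [branch.samples[0].radius]
    for s in branch.samples[1:]:
        if np.linalg.norm(s.position - pts[-1]) > 1e-12:
            pts.append(s.position)
            radii.append(s.radius)
    if branch.is_root_branch:
        if soma_centroid is None:
            raise ValueError("root branches need the soma centroid")
        soma_centroid = np.asarray(soma_centroid, dtype=float)
        if np.linalg.norm(pts[0] - soma_centroid) > 1e-12:
            pts.insert(0, soma_centroid)
            radii.insert(0, root_taper * radii[0])
    if len(pts) < 2:
        raise DegenerateSegment("branch collapses to fewer than 2 distinct points")

    points = np.asarray(pts)
    radii_arr = np.asarray(radii)
    tangents = _polyline_tangents(points)
    frames = _parallel_transport_frames(tangents)

    theta = 2.0 * np.pi * np.arange(sides) / sides
    cos_t, sin_t = np.cos(theta)[:, None], np.sin(theta)[:, None]
    n_rings = len(points)
    verts = np.empty((n_rings * sides + 2, 3))
    for k in range(n_rings):
        e1, e2 = frames[k]
        verts[k * sides : (k + 1) * sides] = (
            points[k] + radii_arr[k] * (cos_t * e1 + sin_t * e2)
        )
    start_cap = n_rings * sides
    end_cap = start_cap + 1
    verts[start_cap] = points[0]
    verts[end_cap] = points[-1]

    faces = []
    for k in range(n_rings - 1):
        a = k * sides
        b = (k + 1) * sides
        for s in range(sides):
            s2 = (s + 1) % sides
            faces.append((a + s, b + s, b + s2))
            faces.append((a + s, b + s2, a + s2))
    for s in range(sides):  # start cap, facing -tangent
        s2 = (s + 1) % sides
        faces.append((start_cap, s2, s))
    last = (n_rings - 1) * sides
    for s in range(sides):  # end cap, facing +tangent
        s2 = (s + 1) % sides
        faces.append((end_cap, last + s, last + s2))

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _prune_by_order(sec: Section, max_order: Optional[int]) -> Optional[Section]:
    if max_order is not None and sec.order > max_order:
        return None
    clone = copy.copy(sec)
    clone.samples = list(sec.samples)
    clone.children = [
        c for c in (_prune_by_order(ch, max_order) for ch in sec.children) if c is not None
    ]
    return clone


def mesh_neuron(m: Morphology, config: MeshConfig = MeshConfig()) -> PiecewiseMesh:
    """Mesh a repaired morphology into its piecewise-watertight components:
    one soma object plus one closed tube per branch of every neurite,
    subject to the per-type branching-order limits.  Runs in linear time in
    the number of sections."""
    out = PiecewiseMesh()
    out.add("soma", "soma", build_soma(m, config.soma))
    centroid = m.soma.centroid
    for n_idx, neurite in enumerate(m.neurites):
        limit = (
            config.max_axon_order
            if neurite.structure is Structure.AXON
            else config.max_dendrite_order
        )
        pruned = _prune_by_order(neurite, limit)
        if pruned is None:
            continue
        for b_idx, branch in enumerate(decompose_branches(pruned)):
            tube = sweep_branch(
                branch,
                sides=config.sides,
                soma_centroid=centroid,
                root_taper=config.root_taper,
            )
            out.add(f"neurite_{n_idx}_branch_{b_idx}", "neurite", tube)
    return out
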