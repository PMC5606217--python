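"""Deterministic synthetic morphologies, artifact injection and toy meshes.

Every stage of the pipeline is testable without downloads: this module
grows random (but seed-stable) neuron skeletons that mimic digitized
reconstructions — neurites rooted on the soma sphere, sections as
random-walk poly-lines, radii tapering at bifurcations with one child
deliberately thicker so the largest-radius branch decomposition is
nontrivial — and can inject each of the three repairable artifact classes
on demand.  A few analytic meshes with known volume/topology serve as
voxelizer and validator oracles.

Randomness comes exclusively from numpy's counter-based Philox generator,
so fixtures are bit-stable across platforms for a given seed.  The shapes
are geometric stand-ins: no attempt is made to match biological
morphometry distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .morphology import MorphSample, Morphology, Section, SomaGeometry, Structure
from .repair import angular_radius
from .soma import make_icosphere

__all__ = [
    "MorphogenParams",
    "generate_morphology",
    "inject_artifacts",
    "toy_mesh",
]


@dataclass
class MorphogenParams:
    """Knobs of the morphology generator.

    ``segment_length`` (μm) is the mean random-walk step; ``taper`` scales
    child radii at bifurcations; ``branch_prob`` is the chance a section
    below ``max_order`` bifurcates.  Defaults give a small multipolar cell:
    a 5 μm soma with three neurites of up to third order, primary dendrites
    around 1.25 μm radius.
    """

    n_neurites: int = 3
    max_order: int = 3
    branch_prob: float = 0.7
    segment_length: float = 5.0
    taper: float = 0.8
    soma_radius: float = 5.0
    seed: int = 0
    segments_per_section: int = 4
    start_radius_fraction: float = 0.25


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _spread_directions(rng: np.random.Generator, n: int, min_angle: float) -> list[np.ndarray]:
    """Sample n unit vectors pairwise separated by at least ``min_angle``
    (best effort: gives up the constraint after 200 rejections)."""
    dirs: list[np.ndarray] = []
    while len(dirs) < n:
        for _ in range(200):
            u = _random_unit(rng)
            if all(np.arccos(np.clip(u @ d, -1, 1)) > min_angle for d in dirs):
                break
        dirs.append(u)
    return dirs


def generate_morphology(p: MorphogenParams) -> Morphology:
    """Grow a random morphology: soma at the origin, ``n_neurites``
    random-walk trees starting on the soma sphere.  Deterministic per
    seed."""
    rng = _rng(p.seed)
    soma = SomaGeometry(centroid=np.zeros(3), mean_radius=p.soma_radius)
    next_id = [2]  # id 1 is reserved for the soma sample on SWC export

    def new_sample(pos, radius, structure) -> MorphSample:
        s = MorphSample(next_id[0], structure, pos, max(radius, 0.05))
        next_id[0] += 1
        return s

    def grow_section(
        head: MorphSample, direction: np.ndarray, radius: float, order: int, structure
    ) -> Section:
        samples = [head]
        pos = head.position.copy()
        d = direction.copy()
        for _ in range(p.segments_per_section):
            d = _unit(d + 0.3 * rng.normal(size=3))
            pos = pos + p.segment_length * rng.uniform(0.7, 1.3) * d
            samples.append(new_sample(pos, radius, structure))
        sec = Section(samples=samples, order=order)
        if order < p.max_order and rng.random() < p.branch_prob:
            base = radius * p.taper
            thick_first = rng.random() < 0.5
            radii = (base, 0.7 * base) if thick_first else (0.7 * base, base)
            for child_r in radii:
                cd = _unit(d + 0.6 * rng.normal(size=3))
                child = grow_section(samples[-1], cd, child_r, order + 1, structure)
                sec.children.append(child)
        return sec

    structures = [Structure.AXON, Structure.BASAL_DENDRITE, Structure.APICAL_DENDRITE]
    r0 = p.start_radius_fraction * p.soma_radius
    min_sep = 2.0 * angular_radius(r0, p.soma_radius) * 1.2
    dirs = _spread_directions(rng, p.n_neurites, min_sep)
    neurites = []
    for k, u in enumerate(dirs):
        structure = structures[k % len(structures)]
        head = new_sample(p.soma_radius * u, r0, structure)
        neurites.append(grow_section(head, u, r0, 1, structure))
    return Morphology(soma=soma, neurites=neurites)


def inject_artifacts(m: Morphology, kinds, seed: int = 0) -> Morphology:
    """Corrupt a clean morphology with the requested artifact classes.

    ``disconnected``: translate a first-order start beyond twice the soma
    radius.  ``overlapping``: rigidly rotate one neurite so its start
    direction lands inside another's footprint.  ``internal``: prepend
    samples inside the soma extent.  Each injection is detectable by the
    corresponding repair operation.
    """
    import copy

    kinds = set(kinds)
    allowed = {"disconnected", "overlapping", "internal"}
    if not kinds:
        raise ValueError("kinds must be a non-empty subset of " + str(allowed))
    if kinds - allowed:
        raise ValueError(f"unknown artifact kinds: {kinds - allowed}")
    m = copy.deepcopy(m)
    rng = _rng(seed)
    c = m.soma.centroid
    order = sorted(kinds)
    picks = rng.choice(len(m.neurites), size=len(order), replace=False)
    max_id = 1 + max(s.id for sec in m.sections() for s in sec.samples)

    for kind, idx in zip(order, picks):
        sec = m.neurites[int(idx)]
        u = _unit(sec.start.position - c)
        if kind == "disconnected":
            sec.start.position = c + 2.5 * m.soma.mean_radius * u
        elif kind == "internal":
            for frac in (0.7, 0.4):
                s = MorphSample(
                    max_id, sec.structure, c + frac * m.soma.mean_radius * u,
                    sec.start.radius,
                )
                max_id += 1
                sec.samples.insert(0, s)
        elif kind == "overlapping":
            target = m.neurites[(int(idx) + 1) % len(m.neurites)]
            if target is sec:  # single-neurite cell: nothing to overlap with
                continue
            v = _unit(target.start.position - c)
            axis = np.cross(u, v)
            s_norm = np.linalg.norm(axis)
            if s_norm < 1e-12:
                continue
            axis /= s_norm
            ang = np.arccos(np.clip(u @ v, -1, 1))
            # leave a small residual angle so starts do not coincide
            ang *= 0.9
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
            for sub in sec.walk():
                for s in sub.samples:
                    s.position = c + R @ (s.position - c)
    return m


def _ngon_prism(radius: float, length: float, sides: int) -> trimesh.Trimesh:
    theta = 2 * np.pi * np.arange(sides) / sides
    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    verts = np.vstack(
        [
            np.column_stack([ring, np.zeros(sides)]),
            np.column_stack([ring, np.full(sides, length)]),
            [[0, 0, 0], [0, 0, length]],
        ]
    )
    faces = []
    bot_c, top_c = 2 * sides, 2 * sides + 1
    for s in range(sides):
        s2 = (s + 1) % sides
        faces += [(s, sides + s, sides + s2), (s, sides + s2, s2)]
        faces += [(bot_c, s2, s), (top_c, sides + s, sides + s2)]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _two_cubes_shared_edge() -> trimesh.Trimesh:
    a = trimesh.creation.box(extents=(1, 1, 1)).apply_translation((0.5, 0.5, 0.5))
    b = trimesh.creation.box(extents=(1, 1, 1)).apply_translation((1.5, 1.5, 0.5))
    verts = np.vstack([a.vertices, b.vertices])
    faces = np.vstack([a.faces, b.faces + len(a.vertices)])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # weld the two vertices along the shared edge x=1, y=1, z∈{0,1}
    mesh.merge_vertices(merge_tex=True, merge_norm=True)
    return mesh


def toy_mesh(shape: str, **params) -> trimesh.Trimesh:
    """Analytic test meshes with known volume, area and topology.

    Shapes: ``icosphere`` (radius, subdivisions), ``box`` (extents),
    ``cylinder`` (radius, length, sides — an exact n-gon prism),
    ``torus`` (major_radius, minor_radius) and ``two_cubes_shared_edge``
    (exactly one non-manifold edge and two non-manifold vertices).
    """
    if shape == "icosphere":
        return make_icosphere(
            params.get("center", (0, 0, 0)),
            params.get("radius", 1.0),
            params.get("subdivisions", 3),
        )
    if shape == "box":
        return trimesh.creation.box(extents=params.get("extents", (1, 1, 1)))
    if shape == "cylinder":
        return _ngon_prism(
            params.get("radius", 1.0), params.get("length", 2.0), params.get("sides", 16)
        )
    if shape == "torus":
        return trimesh.creation.torus(
            major_radius=params.get("major_radius", 3.0),
            minor_radius=params.get("minor_radius", 1.0),
        )
    if shape == "two_cubes_shared_edge":
        return _two_cubes_shared_edge()
    raise ValueError(f"unknown toy shape: {shape}")
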