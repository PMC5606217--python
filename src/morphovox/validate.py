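"""Mesh manifoldness validation.

The voxelization stage is only correct on closed two-manifold surfaces, so
every emitted mesh component is checked for the three defect classes a
mesh inspector reports:

* *boundary edges* — edges with exactly one incident face (holes);
* *non-manifold edges* — edges with three or more incident faces;
* *non-manifold vertices* — vertices whose incident faces do not form a
  single edge-connected fan (e.g. two cones sharing only their apex), or
  that touch a non-manifold edge.

A watertight component reports (0, 0, 0).
"""

from __future__ import annotations

from collections import defaultdict
from typing import NamedTuple

import numpy as np
import trimesh


class WatertightReport(NamedTuple):
    non_manifold_edges: int
    non_manifold_vertices: int
    boundary_edges: int

    @property
    def is_watertight(self) -> bool:
        return self == (0, 0, 0)


def validate_watertight(mesh: trimesh.Trimesh) -> WatertightReport:
    """Count boundary edges, non-manifold edges and non-manifold vertices
    of an indexed triangle mesh."""
    faces = np.asarray(mesh.faces)
    if len(faces) == 0:
        return WatertightReport(0, 0, 0)

    edge_faces: dict[tuple[int, int], list[int]] = defaultdict(list)
    vertex_faces: dict[int, list[int]] = defaultdict(list)
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces[(min(u, v), max(u, v))].append(fi)
        for v in (a, b, c):
            vertex_faces[v].append(fi)

    boundary = sum(1 for fs in edge_faces.values() if len(fs) == 1)
    nm_edges = sum(1 for fs in edge_faces.values() if len(fs) >= 3)

    nm_vertex_ids: set[int] = set()
    # endpoints of non-manifold edges are non-manifold vertices
    for (u, v), fs in edge_faces.items():
        if len(fs) >= 3:
            nm_vertex_ids.update((u, v))

    # fan connectivity: faces around a vertex must form one component when
    # glued across manifold (<= 2 incident faces) edges
    for v, fs in vertex_faces.items():
        if v in nm_vertex_ids or len(fs) <= 1:
            continue
        adj: dict[int, list[int]] = {f: [] for f in fs}
        for f in fs:
            a, b, c = faces[f]
            for p, q in ((a, b), (b, c), (c, a)):
                if v not in (p, q):
                    continue
                key = (min(p, q), max(p, q))
                incident = edge_faces[key]
                if len(incident) == 2:
                    other = incident[0] if incident[1] == f else incident[1]
                    adj[f].append(other)
        seen = {fs[0]}
        stack = [fs[0]]
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if len(seen) != len(fs):
            nm_vertex_ids.add(v)

    return WatertightReport(nm_edges, len(nm_vertex_ids), boundary)
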