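"""Independent brute-force oracles used by the tests and the acceptance
script.  Deliberately simple and separate from the library's algorithms."""

from __future__ import annotations

import numpy as np


def ray_parity_inside(mesh, grid) -> np.ndarray:
    """Classify every voxel center of ``grid`` as inside/outside ``mesh``
    by x-ray crossing parity.

    For each (j, k) column the x positions where the column line pierces a
    triangle are collected (2-D point-in-triangle in the yz projection +
    plane intersection); a center is inside iff an odd number of crossings
    lies to its left.  Column coordinates are jittered by an irrational
    hair so rays never hit mesh edges exactly.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces)
    nx, ny, nz = grid.dims
    cx = grid.origin[0] + grid.spacing * (np.arange(nx) + 0.5)
    cy = grid.origin[1] + grid.spacing * (np.arange(ny) + 0.5) + grid.spacing * 1e-6
    cz = grid.origin[2] + grid.spacing * (np.arange(nz) + 0.5) + grid.spacing * np.sqrt(2) * 1e-6

    delta = np.zeros((nx + 1, ny, nz), dtype=np.int64)
    tris = verts[faces]
    for t in tris:
        y0, z0 = t[0, 1], t[0, 2]
        y1, z1 = t[1, 1], t[1, 2]
        y2, z2 = t[2, 1], t[2, 2]
        det = (y1 - y0) * (z2 - z0) - (y2 - y0) * (z1 - z0)
        if abs(det) < 1e-30:
            continue  # degenerate in projection: contributes no parity
        j_lo = np.searchsorted(cy, min(y0, y1, y2))
        j_hi = np.searchsorted(cy, max(y0, y1, y2))
        k_lo = np.searchsorted(cz, min(z0, z1, z2))
        k_hi = np.searchsorted(cz, max(z0, z1, z2))
        if j_lo == j_hi or k_lo == k_hi:
            continue
        yy, zz = np.meshgrid(cy[j_lo:j_hi], cz[k_lo:k_hi], indexing="ij")
        b1 = ((yy - y0) * (z2 - z0) - (y2 - y0) * (zz - z0)) / det
        b2 = ((y1 - y0) * (zz - z0) - (yy - y0) * (z1 - z0)) / det
        hit = (b1 >= 0) & (b2 >= 0) & (b1 + b2 <= 1)
        if not hit.any():
            continue
        x_int = t[0, 0] + b1 * (t[1, 0] - t[0, 0]) + b2 * (t[2, 0] - t[0, 0])
        jj, kk = np.nonzero(hit)
        i_star = np.searchsorted(cx, x_int[jj, kk])
        np.add.at(delta, (i_star, jj + j_lo, kk + k_lo), 1)
    crossings_left = np.cumsum(delta, axis=0)[:nx]
    return (crossings_left % 2).astype(bool)


def stack_trace_branches(neurite) -> list[list[int]]:
    """Hand-executed largest-radius-continuation partition, as section
    index lists (DFS indexing), written as a literal stack machine."""
    order = {id(s): i for i, s in enumerate(neurite.walk())}
    out: list[list[int]] = []
    stack = [neurite]
    while stack:
        sec = stack.pop()
        path = [order[id(sec)]]
        while sec.children:
            kids = sorted(
                range(len(sec.children)),
                key=lambda c: (-sec.children[c].samples[1].radius, c),
            )
            for c in kids[1:][::-1]:
                stack.append(sec.children[c])
            sec = sec.children[kids[0]]
            path.append(order[id(sec)])
        out.append(path)
    return out
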