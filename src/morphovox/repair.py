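"""Detection and repair of the three soma-adjacent skeleton artifacts.

Digitized morphologies frequently carry reconstruction errors that break
surface meshing near the cell body:

1. *Disconnected branches* — the first sample of a first-order section sits
   far away from the soma.  Fixed by pulling the sample back to the soma
   extent along its original direction from the centroid.
2. *Overlapping first-order sections* — two or more branches would drive the
   same patch of the soma surface during soft-body growth.  Within each
   cluster of mutually overlapping sections only the thickest one is marked
   *primary*; the rest are demoted (still meshed later, with a conic root
   connection to the soma centroid).
3. *Branches intersecting the soma* — samples of a first-order section lying
   inside the soma extent are removed outright.

The repair chain runs in that fixed order, is idempotent, never changes
radii, never adds samples, and never touches sections of order >= 2.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDirection
from .morphology import Morphology, Section

__all__ = [
    "RepairReport",
    "angular_radius",
    "sections_overlap",
    "repair_disconnected",
    "mark_primary_branches",
    "remove_internal_samples",
    "repair",
]


@dataclass
class RepairReport:
    """Full audit of the mutations a repair pass performed."""

    relocated_samples: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)
    demoted_branches: list[tuple[int, str]] = field(default_factory=list)
    removed_samples: list[int] = field(default_factory=list)

    def merge(self, other: "RepairReport") -> "RepairReport":
        return RepairReport(
            self.relocated_samples + other.relocated_samples,
            self.demoted_branches + other.demoted_branches,
            self.removed_samples + other.removed_samples,
        )

    def is_empty(self) -> bool:
        return not (self.relocated_samples or self.demoted_branches or self.removed_samples)

    def to_json(self) -> str:
        return json.dumps(
            {
                "relocated_samples": [
                    {"id": i, "old": list(map(float, a)), "new": list(map(float, b))}
                    for i, a, b in self.relocated_samples
                ],
                "demoted_branches": [
                    {"section": i, "reason": r} for i, r in self.demoted_branches
                ],
                "removed_samples": list(self.removed_samples),
            },
            indent=2,
        )


def angular_radius(radius: float, distance: float) -> float:
    """Half-angle of the spherical footprint of a cross-section of the given
    radius seen from the soma centroid at the given distance."""
    return float(np.arcsin(min(1.0, radius / distance)))


def _start_geometry(soma_centroid: np.ndarray, sec: Section):
    v = sec.start.position - soma_centroid
    d = float(np.linalg.norm(v))
    if d == 0.0:
        raise DegenerateDirection(
            "first-order sample coincides with the soma centroid"
        )
    return v / d, d


def sections_overlap(soma_centroid: np.ndarray, a: Section, b: Section) -> bool:
    """Two first-order sections overlap when their spherical footprints on
    the soma surface intersect: the angle between their start directions is
    smaller than the sum of their angular radii."""
    ua, da = _start_geometry(soma_centroid, a)
    ub, db = _start_geometry(soma_centroid, b)
    ang = float(np.arccos(np.clip(ua @ ub, -1.0, 1.0)))
    return ang < angular_radius(a.start.radius, da) + angular_radius(b.start.radius, db)


def repair_disconnected(m: Morphology) -> tuple[Morphology, RepairReport]:
    """Pull disconnected first-order start samples back to the soma extent.

    Any first-order section whose first sample lies farther from the soma
    centroid than the extent radius (farthest 2-D profile point, falling
    back to the mean radius) has that sample relocated to the extent
    distance along its original direction.  All other samples untouched.
    """
    m = copy.deepcopy(m)
    report = RepairReport()
    d_max = m.soma.extent_radius
    c = m.soma.centroid
    for sec in m.neurites:
        u, d = _start_geometry(c, sec)
        # relative epsilon: starts sitting exactly on the extent are sound
        if d > d_max * (1.0 + 1e-9):
            old = sec.start.position.copy()
            sec.start.position = c + d_max * u
            report.relocated_samples.append((sec.start.id, old, sec.start.position.copy()))
    return m, report


def mark_primary_branches(m: Morphology) -> tuple[Morphology, RepairReport]:
    """Flag exactly one primary section per cluster of overlapping
    first-order sections (the one with the largest start radius; ties break
    by lowest section index).  Non-overlapping sections are primary."""
    m = copy.deepcopy(m)
    report = RepairReport()
    n = len(m.neurites)
    # union-find over the overlap graph
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sections_overlap(m.soma.centroid, m.neurites[i], m.neurites[j]):
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    for members in clusters.values():
        best = max(members, key=lambda i: (m.neurites[i].start.radius, -i))
        for i in members:
            m.neurites[i].is_primary = i == best
            if i != best:
                report.demoted_branches.append((i, "overlaps a thicker first-order section"))
    return m, report


def remove_internal_samples(m: Morphology) -> tuple[Morphology, RepairReport]:
    """Delete first-order samples lying inside the soma extent
    (distance to centroid < mean radius); sections left with fewer than two
    samples are dropped together with their subtree and reported."""
    m = copy.deepcopy(m)
    report = RepairReport()
    c, r_soma = m.soma.centroid, m.soma.mean_radius
    keep: list[Section] = []
    for idx, sec in enumerate(m.neurites):
        survivors = []
        for k, s in enumerate(sec.samples):
            inside = float(np.linalg.norm(s.position - c)) < r_soma
            # the tail sample is shared with child sections' heads and must
            # survive while children exist
            if inside and not (sec.children and k == len(sec.samples) - 1):
                report.removed_samples.append(s.id)
            else:
                survivors.append(s)
        if len(survivors) >= 2:
            sec.samples = survivors
            keep.append(sec)
        else:
            report.demoted_branches.append((idx, "entirely inside the soma extent"))
    m.neurites = keep
    return m, report


def repair(m: Morphology) -> tuple[Morphology, RepairReport]:
    """Full artifact repair: disconnected fix, primary marking, internal
    sample removal, in that order."""
    m, r1 = repair_disconnected(m)
    m, r2 = mark_primary_branches(m)
    m, r3 = remove_internal_samples(m)
    return m, r1.merge(r2).merge(r3)
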