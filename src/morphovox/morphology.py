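"""Morphology container and SWC reader/writer.

A digitized neuron skeleton is a tree of radius-tagged 3-D sample points
rooted at the cell body (soma).  Two consecutive samples form a *segment*;
a maximal non-bifurcating run of segments forms a *section*; sections
attached to the soma are *first order*.  The soma itself is collapsed to a
centroid, a mean radius and (when the file stores a type-1 contour ring)
an ordered 2-D profile.

All coordinates and radii are micrometres, kept exactly as found in the
file; no unit inference is performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import EmptyMorphology, InvalidMorphology, MalformedInput

ROOT_PARENT = -1


class Structure(enum.Enum):
    """SWC structure identifiers; codes outside 1-4 map to OTHER."""

    SOMA = 1
    AXON = 2
    BASAL_DENDRITE = 3
    APICAL_DENDRITE = 4
    OTHER = 0

    @classmethod
    def from_swc(cls, code: int) -> "Structure":
        try:
            return cls(code) if code in (1, 2, 3, 4) else cls.OTHER
        except ValueError:  # pragma: no cover - guarded above
            return cls.OTHER

    def to_swc(self) -> int:
        return self.value if self is not Structure.OTHER else 5


@dataclass
class MorphSample:
    """One skeleton point: a position and the local cross-section radius."""

    id: int
    structure: Structure
    position: np.ndarray  # shape (3,), μm
    radius: float  # μm
    parent_id: int = ROOT_PARENT

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise InvalidMorphology(f"sample {self.id}: position must be a 3-vector")
        if not self.radius > 0:
            raise InvalidMorphology(f"sample {self.id}: radius must be > 0")
        if self.parent_id == self.id:
            raise InvalidMorphology(f"sample {self.id}: sample is its own parent")


@dataclass
class SomaGeometry:
    """Soma description: centroid, mean radius and optional 2-D contour."""

    centroid: np.ndarray  # (3,), μm
    mean_radius: float  # μm
    profile_2d: Optional[np.ndarray] = None  # (n>=3, 3), μm

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if not self.mean_radius > 0:
            raise InvalidMorphology("soma mean_radius must be > 0")
        if self.profile_2d is not None:
            self.profile_2d = np.asarray(self.profile_2d, dtype=float)
            if self.profile_2d.ndim != 2 or self.profile_2d.shape[0] < 3:
                raise InvalidMorphology("soma profile needs >= 3 points")

    @property
    def extent_radius(self) -> float:
        """Distance from the centroid to the farthest profile point, or the
        mean radius when no contour is stored."""
        if self.profile_2d is None:
            return self.mean_radius
        return float(np.linalg.norm(self.profile_2d - self.centroid, axis=1).max())


@dataclass
class Section:
    """A non-bifurcating run of samples.

    The first sample of a child section is shared with (is the last sample
    of) its parent section, so segments are emitted per section without
    double counting tree edges.
    """

    samples: list[MorphSample]
    order: int
    children: list["Section"] = field(default_factory=list)
    is_primary: bool = True

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise InvalidMorphology("a section needs at least 2 samples")

    @property
    def structure(self) -> Structure:
        return self.samples[-1].structure

    @property
    def start(self) -> MorphSample:
        return self.samples[0]

    def walk(self) -> Iterator["Section"]:
        """Depth-first iteration over this section and its descendants."""
        stack = [self]
        while stack:
            sec = stack.pop()
            yield sec
            stack.extend(reversed(sec.children))


@dataclass
class Morphology:
    """A soma plus a forest of first-order sections (one root per neurite)."""

    soma: SomaGeometry
    neurites: list[Section] = field(default_factory=list)

    def sections(self) -> Iterator[Section]:
        for root in self.neurites:
            yield from root.walk()

    def n_sections(self) -> int:
        return sum(1 for _ in self.sections())


def iter_segments(m: Morphology) -> Iterator[tuple[MorphSample, MorphSample]]:
    """Yield every parent-child sample pair (segment) exactly once.

    Segments are emitted per section; because a child section's head is the
    shared bifurcation sample, the pair (bifurcation, first child sample)
    appears only in the child section.
    """
    for sec in m.sections():
        for a, b in zip(sec.samples[:-1], sec.samples[1:]):
            yield a, b


def _build_sections(
    root_sample: MorphSample,
    samples: dict[int, MorphSample],
    children: dict[int, list[int]],
    order: int,
) -> Optional[Section]:
    """Cut the sample tree at bifurcations, starting a section at
    ``root_sample`` (which is shared with the parent section's tail)."""
    chain = [root_sample]
    cur = root_sample.id
    while True:
        kids = children.get(cur, [])
        if len(kids) == 1:
            nxt = samples[kids[0]]
            if not np.array_equal(nxt.position, chain[-1].position):
                chain.append(nxt)
            else:  # zero-length segment: merge the duplicate point
                chain[-1] = nxt
            cur = nxt.id
        else:
            break
    if len(chain) < 2:
        return None
    sec = Section(samples=chain, order=order)
    for kid in children.get(cur, []):
        child = _build_sections(samples[kid], samples, children, order + 1)
        if child is not None:
            # child sections start at the shared bifurcation sample
            child.samples.insert(0, chain[-1])
            sec.children.append(child)
    return sec


def read_swc(path, soma_profile: str = "auto") -> Morphology:
    """Parse a standard 7-column SWC file into a :class:`Morphology`.

    Type-1 (soma) samples are collapsed into centroid + mean radius; with
    ``soma_profile="auto"`` three or more soma samples are additionally kept
    as an ordered 2-D contour, ``"never"`` discards the contour.  Sections
    are built by cutting the sample tree at bifurcations.  Accepts LF/CRLF,
    arbitrary whitespace and out-of-order ids.
    """
    if soma_profile not in ("auto", "never"):
        raise ValueError("soma_profile must be 'auto' or 'never'")
    samples: dict[int, MorphSample] = {}
    order_seen: list[int] = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MalformedInput(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                sid = int(cols[0])
                stype = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                parent = int(cols[6])
            except ValueError as exc:
                raise MalformedInput(f"{path}:{lineno}: non-numeric field") from exc
            if sid in samples:
                raise MalformedInput(f"{path}:{lineno}: duplicate id {sid}")
            try:
                samples[sid] = MorphSample(sid, Structure.from_swc(stype), (x, y, z), r, parent)
            except InvalidMorphology as exc:
                raise MalformedInput(f"{path}:{lineno}: {exc}") from exc
            order_seen.append(sid)
    if not samples:
        raise MalformedInput(f"{path}: no data rows")

    children: dict[int, list[int]] = {}
    for sid in order_seen:
        s = samples[sid]
        if s.parent_id != ROOT_PARENT:
            if s.parent_id not in samples:
                raise MalformedInput(f"sample {sid}: dangling parent {s.parent_id}")
            children.setdefault(s.parent_id, []).append(sid)

    # cycle check: every sample must reach a root
    for sid in order_seen:
        seen = set()
        cur = sid
        while cur != ROOT_PARENT:
            if cur in seen:
                raise MalformedInput(f"cycle involving sample {sid}")
            seen.add(cur)
            cur = samples[cur].parent_id

    soma_samples = [samples[sid] for sid in order_seen if samples[sid].structure is Structure.SOMA]
    if not soma_samples:
        raise EmptyMorphology(f"{path}: no soma sample")
    soma_pos = np.array([s.position for s in soma_samples])
    profile = None
    if soma_profile == "auto" and len(soma_samples) >= 3:
        profile = soma_pos.copy()
    soma = SomaGeometry(
        centroid=soma_pos.mean(axis=0),
        mean_radius=float(np.mean([s.radius for s in soma_samples])),
        profile_2d=profile,
    )

    soma_ids = {s.id for s in soma_samples}
    neurites: list[Section] = []
    for sid in order_seen:
        s = samples[sid]
        if s.id in soma_ids:
            continue
        if s.parent_id in soma_ids or s.parent_id == ROOT_PARENT:
            root = _build_sections(s, samples, children, order=1)
            if root is not None:
                neurites.append(root)
    return Morphology(soma=soma, neurites=neurites)


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard 7-column SWC (6 significant digits).

    Round-trips through :func:`read_swc` up to sample renumbering and
    float formatting.  Raises :class:`InvalidMorphology` on invalid input.
    """
    if not m.soma.mean_radius > 0:
        raise InvalidMorphology("soma mean_radius must be > 0")
    for sec in m.sections():
        for s in sec.samples:
            if not s.radius > 0:
                raise InvalidMorphology(f"sample {s.id}: radius must be > 0")

    lines = ["# generated by morphovox", "# id type x y z radius parent"]
    next_id = 1

    def fmt(i, t, p, r, parent):
        x, y, z = p
        return f"{i} {t} {x:.6g} {y:.6g} {z:.6g} {r:.6g} {parent}"

    if m.soma.profile_2d is not None:
        soma_anchor = next_id
        for k, p in enumerate(m.soma.profile_2d):
            parent = ROOT_PARENT if k == 0 else soma_anchor
            lines.append(fmt(next_id, 1, p, m.soma.mean_radius, parent))
            next_id += 1
    else:
        soma_anchor = next_id
        lines.append(fmt(next_id, 1, m.soma.centroid, m.soma.mean_radius, ROOT_PARENT))
        next_id += 1

    def emit(sec: Section, head_id: int | None) -> None:
        nonlocal next_id
        start = 0 if head_id is None else 1  # skip the shared bifurcation sample
        prev = soma_anchor if head_id is None else head_id
        for s in sec.samples[start:]:
            lines.append(fmt(next_id, s.structure.to_swc(), s.position, s.radius, prev))
            prev = next_id
            next_id += 1
        tail = prev
        for child in sec.children:
            emit(child, tail)

    for root in m.neurites:
        emit(root, None)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
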