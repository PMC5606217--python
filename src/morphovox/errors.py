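"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`MorphovoxError` so callers can
catch pipeline failures without masking programming errors.
"""


class MorphovoxError(Exception):
    """Base class for all pipeline errors."""


class MalformedInput(MorphovoxError):
    """An input file violates its format (SWC column count, dangling
    parent, cycle, non-numeric field)."""


class EmptyMorphology(MorphovoxError):
    """A morphology without any soma sample."""


class InvalidMorphology(MorphovoxError):
    """A morphology violating a structural invariant (e.g. radius <= 0)."""


class DegenerateDirection(MorphovoxError):
    """A first-order sample coincides with the soma centroid, so its
    direction from the soma is undefined."""


class EmptyFootprint(MorphovoxError):
    """A branch cross-section projects onto the icosphere without
    capturing any vertex; the subdivision level is too coarse."""


class NonConvergence(MorphovoxError):
    """The soma spring relaxation did not reach the force residual
    threshold within the iteration budget."""


class DegenerateSegment(MorphovoxError):
    """A branch collapses to fewer than two distinct points."""


class InvalidSides(MorphovoxError):
    """Tube cross-sections need at least 3 sides."""


class EmptyInput(MorphovoxError):
    """An operation requiring at least one mesh/neuron received none."""


class ResolutionOverflow(MorphovoxError):
    """The requested grid exceeds the configured memory cap."""


class OutOfBounds(MorphovoxError):
    """Geometry falls outside the voxel grid."""


class GeometryMismatch(MorphovoxError):
    """Volumes that must share origin/spacing/dims do not."""


class UnknownLabel(MorphovoxError):
    """A label id is missing from the optical-property table."""
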