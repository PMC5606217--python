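"""Volume annotation and a simplified brightfield projector.

Once the circuit occupies a solid binary volume per neuron, the voxels are
*tagged*: each voxel carries a small-integer label (0 = extracellular)
that maps, through a property table, to the optical behaviour of the
structure filling it — e.g. the broadband absorption of a Golgi silver
stain.

The projector is an orthographic, absorption-only Beer–Lambert model of a
transmitted-light (brightfield) microscope: per pixel and wavelength,

    T(λ) = exp(−Σ_ray μa(label, λ) · spacing),

composited against a light-source spectrum into an RGB image.  Scattering,
diffraction and defocus optics are deliberately out of scope; a focal
stack is emulated by slab-wise projection with a Gaussian out-of-focus
blur that grows with slab distance.  Absorption coefficients are
illustrative defaults, not measured values, and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryMismatch, UnknownLabel
from .volumes import BitVolume

__all__ = [
    "OpticalProperties",
    "LabelVolume",
    "LightSource",
    "GOLGI_STAIN",
    "TRANSPARENT",
    "XENON_LAMP",
    "annotate",
    "brightfield_project",
    "focal_stack",
    "BrightfieldImage",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class OpticalProperties:
    """Spectral behaviour of a labelled structure.

    ``absorption_spectrum``: (wavelength nm, μa in 1/μm) pairs with
    strictly increasing wavelengths.  Scattering and anisotropy are carried
    for completeness (fluorescence/optogenetic use cases) but ignored by
    the absorption-only projector.
    """

    absorption_spectrum: Sequence[tuple[float, float]]
    scattering_spectrum: Optional[Sequence[tuple[float, float]]] = None
    anisotropy: Optional[float] = None

    def __post_init__(self) -> None:
        wl = [w for w, _ in self.absorption_spectrum]
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        if any(mu < 0 for _, mu in self.absorption_spectrum):
            raise ValueError("absorption coefficients must be >= 0")
        if self.anisotropy is not None and not -1.0 <= self.anisotropy <= 1.0:
            raise ValueError("anisotropy must lie in [-1, 1]")

    def mu_a(self, wavelengths: np.ndarray) -> np.ndarray:
        wl, mu = np.asarray(self.absorption_spectrum, dtype=float).T
        return np.interp(wavelengths, wl, mu)


@dataclass
class LightSource:
    """Relative spectral power of the illuminant."""

    spectrum: Sequence[tuple[float, float]]
    name: str = "source"

    def __post_init__(self) -> None:
        powers = [p for _, p in self.spectrum]
        if any(p < 0 for p in powers) or not any(p > 0 for p in powers):
            raise ValueError("source powers must be >= 0 and not all zero")

    def power(self, wavelengths: np.ndarray) -> np.ndarray:
        wl, p = np.asarray(self.spectrum, dtype=float).T
        return np.interp(wavelengths, wl, p)


#: Broadband absorber standing in for Golgi's silver stain (flat μa,
#: illustrative value — the stain's true coefficients are not tabulated).
GOLGI_STAIN = OpticalProperties(absorption_spectrum=[(380.0, 0.05), (720.0, 0.05)])

#: Non-absorbing structure.
TRANSPARENT = OpticalProperties(absorption_spectrum=[(380.0, 0.0), (720.0, 0.0)])

#: Coarse Xenon-arc spectrum, 380–720 nm: bright and nearly flat in the
#: visible with mild blue emphasis.  Illustrative, not metrological.
XENON_LAMP = LightSource(
    spectrum=[
        (380.0, 0.85), (420.0, 0.95), (460.0, 1.00), (500.0, 0.98),
        (540.0, 0.95), (580.0, 0.93), (620.0, 0.92), (660.0, 0.90),
        (700.0, 0.88), (720.0, 0.87),
    ],
    name="xenon",
)


class LabelVolume:
    """Per-voxel uint16 labels on a BitVolume geometry plus the property
    table mapping each nonzero label to (structure name, optics)."""

    def __init__(self, origin, spacing: float, labels: np.ndarray, table: dict):
        self.origin = np.asarray(origin, dtype=float)
        self.spacing = float(spacing)
        self.labels = np.asarray(labels, dtype=np.uint16)
        assert self.labels.ndim == 3
        self.table = dict(table)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.table)
        if missing:
            raise UnknownLabel(f"labels missing from table: {sorted(missing)}")

    @property
    def dims(self):
        return self.labels.shape

    def save_nrrd(self, path) -> None:
        nx, ny, nz = self.labels.shape
        header = (
            "NRRD0004\n"
            "type: uint16\n"
            "dimension: 3\n"
            f"sizes: {nx} {ny} {nz}\n"
            "encoding: raw\n"
            "endian: little\n"
            f"space origin: ({self.origin[0]},{self.origin[1]},{self.origin[2]})\n"
            f"space directions: ({self.spacing},0,0) (0,{self.spacing},0) (0,0,{self.spacing})\n"
            "\n"
        )
        with open(path, "wb") as fh:
            fh.write(header.encode())
            fh.write(self.labels.transpose(2, 1, 0).astype("<u2").tobytes())


def annotate(
    neuron_volumes: Sequence[tuple[BitVolume, int]],
    table: dict,
) -> LabelVolume:
    """Tag solid volumes into one label volume.

    All volumes must share geometry; where neurons overlap, the
    last-listed one wins (highest priority).  Every used label must be in
    ``table`` and be >= 1.
    """
    if not neuron_volumes:
        raise GeometryMismatch("no volumes to annotate")
    first = neuron_volumes[0][0]
    labels = np.zeros(first.dims, dtype=np.uint16)
    for vol, label in neuron_volumes:
        if label < 1:
            raise UnknownLabel("labels must be >= 1 (0 is extracellular)")
        if label not in table:
            raise UnknownLabel(f"label {label} missing from table")
        if not vol.same_geometry(first):
            raise GeometryMismatch("volumes do not share origin/spacing/dims")
        labels[vol.as_array()] = label
    return LabelVolume(first.origin, first.spacing, labels, table)


def _rgb_weights(wavelengths: np.ndarray) -> np.ndarray:
    """Coarse colour-matching weights: Gaussian R/G/B bands centred at
    600/550/450 nm.  Returns (3, n_wavelengths)."""
    centers = np.array([600.0, 550.0, 450.0])
    sigma = 50.0
    return np.exp(-0.5 * ((wavelengths[None, :] - centers[:, None]) / sigma) ** 2)


@dataclass
class BrightfieldImage:
    """Per-wavelength transmission maps plus a source-weighted RGB
    composite (white = unobstructed illumination)."""

    wavelengths: np.ndarray  # (nw,)
    transmission: np.ndarray  # (nw, h, w) in [0, 1]
    composite: np.ndarray  # (h, w, 3) in [0, 1]


def _optical_density(
    vol: LabelVolume, wavelengths: np.ndarray, axis: int
) -> np.ndarray:
    """Σ μa(label, λ)·spacing along ``axis``: (nw, h, w) optical density."""
    labels = vol.labels
    dens = np.zeros((len(wavelengths),) + tuple(
        d for a, d in enumerate(labels.shape) if a != axis
    ))
    for label, (name, props) in vol.table.items():
        mu = props.mu_a(wavelengths)
        if not mu.any():
            continue
        thickness = (labels == label).sum(axis=axis) * vol.spacing
        dens += mu[:, None, None] * thickness[None, :, :]
    return dens


def _composite(
    transmission: np.ndarray, wavelengths: np.ndarray, source: LightSource
) -> np.ndarray:
    w = _rgb_weights(wavelengths) * source.power(wavelengths)[None, :]
    w = w / w.sum(axis=1, keepdims=True)
    return np.einsum("cw,whx->hxc", w, transmission)


def brightfield_project(
    vol: LabelVolume,
    source: LightSource = XENON_LAMP,
    wavelengths: Optional[Sequence[float]] = None,
    axis: str = "z",
) -> BrightfieldImage:
    """Orthographic Beer–Lambert projection through the labelled volume.

    Per pixel: ``T(λ) = exp(−Σ_along-ray μa(label, λ)·spacing)``; the
    composite weights each wavelength by the source power and a coarse RGB
    colour-matching band.  Pure absorption: no scattering, no defocus.
    """
    wl = np.asarray(
        wavelengths if wavelengths is not None else [450.0, 550.0, 600.0], dtype=float
    )
    dens = _optical_density(vol, wl, _AXIS[axis])
    transmission = np.exp(-dens)
    return BrightfieldImage(wl, transmission, _composite(transmission, wl, source))


def focal_stack(
    vol: LabelVolume,
    source: LightSource = XENON_LAMP,
    axis: str = "z",
    n_planes: int = 1,
    wavelengths: Optional[Sequence[float]] = None,
    blur_per_slab: float = 2.0,
) -> list[BrightfieldImage]:
    """Slab-wise projections emulating refocusing.

    The volume is partitioned into ``n_planes`` slabs along ``axis``; image
    ``i`` keeps slab ``i`` sharp while every other slab's optical density
    is blurred with a Gaussian of σ = ``blur_per_slab`` × (slab distance)
    pixels before compositing the full-thickness attenuation.  With one
    plane this reduces exactly to :func:`brightfield_project`.
    """
    assert n_planes >= 1
    wl = np.asarray(
        wavelengths if wavelengths is not None else [450.0, 550.0, 600.0], dtype=float
    )
    ax = _AXIS[axis]
    n = vol.labels.shape[ax]
    edges = np.linspace(0, n, n_planes + 1).astype(int)
    slab_density = []
    for s in range(n_planes):
        sl = [slice(None)] * 3
        sl[ax] = slice(edges[s], edges[s + 1])
        sub = LabelVolume(vol.origin, vol.spacing, vol.labels[tuple(sl)], vol.table)
        slab_density.append(_optical_density(sub, wl, ax))
    images = []
    for i in range(n_planes):
        total = np.zeros_like(slab_density[0])
        for j, dens in enumerate(slab_density):
            if i == j:
                total += dens
            else:
                sigma = blur_per_slab * abs(i - j)
                total += ndimage.gaussian_filter(dens, sigma=(0, sigma, sigma))
        transmission = np.exp(-total)
        images.append(BrightfieldImage(wl, transmission, _composite(transmission, wl, source)))
    return images
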