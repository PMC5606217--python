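"""Bit-packed occupancy volumes and their on-disk formats.

A :class:`BitVolume` is an axis-aligned, isotropic voxel grid storing one
bit per voxel (LSB-first within each byte), with a physical origin and
spacing in μm.  Voxel ``(i, j, k)`` owns the half-open box
``[origin + spacing·(i,j,k), origin + spacing·(i+1,j+1,k+1))`` and lives at
flat index ``i + nx·(j + ny·k)``.

Writers cover a minimal NRRD (text header + raw payload), raw ``.bin`` with
a JSON sidecar, an 8-bit TIFF stack for visual inspection and PNG
maximum-intensity projections for QA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyInput, ResolutionOverflow

DEFAULT_MEMORY_CAP = 2 << 30  # bytes of payload


@dataclass
class AABB:
    """Axis-aligned bounding box in μm."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, dtype=float)
        self.max_corner = np.asarray(self.max_corner, dtype=float)
        assert np.all(self.min_corner <= self.max_corner)

    @property
    def extent(self) -> np.ndarray:
        return self.max_corner - self.min_corner

    def union(self, other: "AABB") -> "AABB":
        return AABB(
            np.minimum(self.min_corner, other.min_corner),
            np.maximum(self.max_corner, other.max_corner),
        )


class BitVolume:
    """Bit-packed binary occupancy grid with physical placement."""

    def __init__(self, origin, spacing: float, dims, payload: np.ndarray | None = None):
        self.origin = np.asarray(origin, dtype=float)
        self.spacing = float(spacing)
        self.dims = tuple(int(d) for d in dims)
        assert len(self.dims) == 3 and all(d >= 1 for d in self.dims)
        n_bytes = (self.n_voxels + 7) // 8
        if payload is None:
            payload = np.zeros(n_bytes, dtype=np.uint8)
        else:
            payload = np.asarray(payload, dtype=np.uint8)
            assert payload.size == n_bytes
        self.payload = payload

    # --- geometry -----------------------------------------------------
    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def flat_index(self, i, j, k) -> np.ndarray:
        nx, ny, _ = self.dims
        return np.asarray(i) + nx * (np.asarray(j) + ny * np.asarray(k))

    def voxel_center(self, i, j, k) -> np.ndarray:
        ijk = np.stack(np.broadcast_arrays(i, j, k), axis=-1)
        return self.origin + self.spacing * (ijk + 0.5)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(points) - self.origin) / self.spacing).astype(int)

    def same_geometry(self, other: "BitVolume") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.spacing, other.spacing)
        )

    # --- bit access ----------------------------------------------------
    def set_flat(self, idx: np.ndarray) -> None:
        """Set bits at flat indices.  Idempotent; duplicates are safe (the
        scatter is a single bitwise-OR reduction, so no set is ever lost)."""
        idx = np.asarray(idx, dtype=np.int64)
        np.bitwise_or.at(self.payload, idx >> 3, (1 << (idx & 7)).astype(np.uint8))

    def get_flat(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.int64)
        return (self.payload[idx >> 3] >> (idx & 7).astype(np.uint8)) & 1

    def as_array(self) -> np.ndarray:
        """Unpack to a bool array indexable as ``arr[i, j, k]``."""
        bits = np.unpackbits(self.payload, bitorder="little")[: self.n_voxels]
        nx, ny, nz = self.dims
        return bits.reshape(nz, ny, nx).transpose(2, 1, 0).astype(bool)

    @classmethod
    def from_array(cls, arr: np.ndarray, origin, spacing: float) -> "BitVolume":
        arr = np.asarray(arr, dtype=bool)
        flat = arr.transpose(2, 1, 0).reshape(-1)
        payload = np.packbits(flat, bitorder="little")
        return cls(origin, spacing, arr.shape, payload)

    def count(self) -> int:
        """Number of set voxels (popcount of the payload)."""
        return int(np.unpackbits(self.payload, bitorder="little")[: self.n_voxels].sum())

    def copy(self) -> "BitVolume":
        return BitVolume(self.origin, self.spacing, self.dims, self.payload.copy())

    def __or__(self, other: "BitVolume") -> "BitVolume":
        assert self.same_geometry(other)
        return BitVolume(self.origin, self.spacing, self.dims, self.payload | other.payload)

    # --- writers --------------------------------------------------------
    def save_raw(self, path) -> None:
        """Raw packed payload + JSON sidecar (dims, origin, spacing,
        LSB-first bit order)."""
        path = Path(path)
        path.write_bytes(self.payload.tobytes())
        sidecar = {
            "dims": list(self.dims),
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "bit_order": "lsb_first",
            "flat_index": "i + nx*(j + ny*k)",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    def save_nrrd(self, path) -> None:
        """Minimal NRRD: uint8 0/1 voxels with origin and spacing recorded
        in the header."""
        arr = self.as_array().astype(np.uint8)
        nx, ny, nz = self.dims
        header = (
            "NRRD0004\n"
            "type: uint8\n"
            "dimension: 3\n"
            f"sizes: {nx} {ny} {nz}\n"
            "encoding: raw\n"
            "endian: little\n"
            "space: left-posterior-superior\n"
            f"space origin: ({self.origin[0]},{self.origin[1]},{self.origin[2]})\n"
            f"space directions: ({self.spacing},0,0) (0,{self.spacing},0) (0,0,{self.spacing})\n"
            "\n"
        )
        with open(path, "wb") as fh:
            fh.write(header.encode())
            fh.write(arr.transpose(2, 1, 0).tobytes())  # x fastest

    def save_tiff_stack(self, path) -> None:
        import tifffile

        arr = self.as_array().astype(np.uint8) * 255
        tifffile.imwrite(path, arr.transpose(2, 1, 0))  # pages along z

    def save_projections(self, prefix) -> list[Path]:
        """Write the three maximum-intensity projections as 8-bit PNGs."""
        import imageio.v3 as iio

        arr = self.as_array()
        out = []
        for axis, name in ((0, "x"), (1, "y"), (2, "z")):
            img = (arr.max(axis=axis).T[::-1].astype(np.uint8)) * 255
            p = Path(f"{prefix}_mip_{name}.png")
            iio.imwrite(p, img)
            out.append(p)
        return out


def make_grid(
    bounds: AABB, resolution: int, memory_cap: int = DEFAULT_MEMORY_CAP
) -> BitVolume:
    """Allocate an all-zero grid covering ``bounds`` with the largest axis
    split into ``resolution`` voxels, plus a one-voxel empty margin on all
    sides (so border flood-fill seeds are always exterior)."""
    assert resolution >= 1
    extent = bounds.extent
    largest = float(extent.max())
    if largest <= 0:
        raise EmptyInput("bounding box has zero extent in every axis")
    spacing = largest / resolution
    dims = np.maximum(np.ceil(extent / spacing - 1e-9).astype(int), 1) + 2
    n_bytes = (int(np.prod(dims)) + 7) // 8
    if n_bytes > memory_cap:
        raise ResolutionOverflow(
            f"grid {tuple(dims)} needs {n_bytes} payload bytes, cap is {memory_cap}; "
            "lower the resolution or raise the cap"
        )
    origin = bounds.min_corner - spacing
    return BitVolume(origin, spacing, dims)
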