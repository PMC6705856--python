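"""Voxel-grid geometry shared by series, maps and ROIs.

All stacks handled here are parallel sagittal slice stacks: a slice axis
(index ``s``) plus an in-plane (row, col) grid. Patient coordinates are
reconstructed from the per-slice position, the in-plane origin and the pixel
spacing, which is what mask transfer between two acquisitions needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "GeometryError"]


class GeometryError(ValueError):
    """Raised when two geometries cannot be related (e.g. oblique stacks)."""


@dataclass(frozen=True)
class Geometry:
    """Axis-aligned geometry of a parallel sagittal slice stack.

    Parameters
    ----------
    pixel_spacing:
        In-plane spacing ``(row_mm, col_mm)``.
    slice_thickness:
        Slice thickness in mm.
    slice_positions:
        Position of each slice along the stack axis, in mm. Must be strictly
        monotone.
    origin:
        In-plane patient coordinate (mm) of the center of voxel ``(0, 0)``.
    orientation:
        Stack orientation label; transfers require both geometries to agree.
    posterior:
        In-plane unit vector pointing towards the patient's posterior,
        expressed in (row, col) axes. Used to orient the anterior–posterior
        axis of sub-region partitions.
    """

    pixel_spacing: tuple[float, float]
    slice_thickness: float
    slice_positions: tuple[float, ...]
    origin: tuple[float, float] = (0.0, 0.0)
    orientation: str = "sagittal"
    posterior: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise GeometryError("pixel_spacing must be two positive values (row, col)")
        if self.slice_thickness <= 0:
            raise GeometryError("slice_thickness must be positive")
        pos = np.asarray(self.slice_positions, dtype=float)
        if pos.size == 0:
            raise GeometryError("slice_positions must not be empty")
        if pos.size > 1 and not (np.all(np.diff(pos) > 0) or np.all(np.diff(pos) < 0)):
            raise GeometryError("slice_positions must be strictly monotone")
        p = np.asarray(self.posterior, dtype=float)
        if not np.isclose(np.linalg.norm(p), 1.0):
            raise GeometryError("posterior must be an in-plane unit vector")

    @property
    def n_slices(self) -> int:
        return len(self.slice_positions)

    def inplane_coords(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Patient in-plane coordinates (mm) of voxel centers, shape (n, 2)."""
        r = np.asarray(rows, dtype=float)
        c = np.asarray(cols, dtype=float)
        return np.stack(
            [
                self.origin[0] + r * self.pixel_spacing[0],
                self.origin[1] + c * self.pixel_spacing[1],
            ],
            axis=-1,
        )

    def nearest_inplane_index(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest (row, col) indices for in-plane coordinates, shape (n, 2)."""
        xy = np.asarray(coords, dtype=float)
        rows = np.rint((xy[..., 0] - self.origin[0]) / self.pixel_spacing[0]).astype(int)
        cols = np.rint((xy[..., 1] - self.origin[1]) / self.pixel_spacing[1]).astype(int)
        return rows, cols

    def nearest_slice(self, positions: np.ndarray) -> np.ndarray:
        """Index of the slice whose position is closest to each query (mm)."""
        pos = np.asarray(self.slice_positions, dtype=float)
        q = np.atleast_1d(np.asarray(positions, dtype=float))
        return np.abs(q[:, None] - pos[None, :]).argmin(axis=1)

    def compatible_orientation(self, other: "Geometry") -> bool:
        return (
            self.orientation == other.orientation
            and np.allclose(self.posterior, other.posterior)
        )
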