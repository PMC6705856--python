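"""Semi-automated disc segmentation and geometric ROI transfer.

Discs are outlined slice-by-slice on a structural series with seeded region
growing, optionally tightened with morphological contour contraction (the
reproducible proxy for manual adjustment), then moved onto the T2-map grid
through patient coordinates derived from position and pixel-spacing
information — no image resampling, masks stay categorical.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import Geometry, GeometryError

__all__ = [
    "DiscROI",
    "region_grow",
    "contract_contour",
    "transfer_roi",
    "build_disc_roi",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross element


@dataclass(frozen=True)
class DiscROI:
    """A labeled voxel set for one disc over three consecutive sagittal slices.

    ``mask`` spans the full grid; the three ROI-bearing slices are recorded in
    ``slices``. ``degenerate`` marks ROIs emptied by over-contraction — they
    carry no voxels and must be excluded from analysis. ``strict=False``
    relaxes the per-slice connectivity check, which nearest-neighbor transfer
    onto a finer grid legitimately breaks.
    """

    subject: str
    level: str
    mask: np.ndarray
    geometry: Geometry
    slices: tuple[int, int, int] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)
    degenerate: bool = False
    strict: InitVar[bool] = True

    def __post_init__(self, strict: bool) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be 3-D (slice, row, col)")
        if mask.shape[0] != self.geometry.n_slices:
            raise ValueError("mask slice count must match the geometry")
        object.__setattr__(self, "mask", mask)
        if self.degenerate:
            return
        occupied = np.flatnonzero(mask.any(axis=(1, 2)))
        if occupied.size != 3 or not np.array_equal(occupied, occupied[0] + np.arange(3)):
            raise ValueError("ROI must occupy exactly three consecutive slices")
        if self.slices is None:
            object.__setattr__(self, "slices", tuple(int(s) for s in occupied))
        if strict:
            for s in occupied:
                if measure.label(mask[s], connectivity=2).max() != 1:
                    raise ValueError(f"ROI slice {s} must be a single 8-connected component")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_indices(self) -> np.ndarray:
        """ROI voxel indices as an (n, 3) array of (slice, row, col)."""
        return np.argwhere(self.mask)


def region_grow(image: np.ndarray, seed: tuple[int, int], tolerance: float) -> np.ndarray:
    """Grow an 8-connected region from a seed pixel on one 2-D slice.

    The reference intensity is the mean of the 3×3 neighborhood of the seed
    (clipped at image borders); a pixel belongs to the region when its
    intensity differs from the reference by at most ``tolerance × reference``.
    The result is the maximal 8-connected such set containing the seed and is
    deterministic for fixed inputs.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    r, c = seed
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"seed {seed!r} is outside the image grid {img.shape}")

    window = img[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
    reference = float(window.mean())
    accept = np.abs(img - reference) <= tolerance * abs(reference)
    labels = measure.label(accept, connectivity=2)
    if labels[r, c] == 0:  # seed itself rejected (pathological reference)
        return np.zeros_like(accept)
    return labels == labels[r, c]


def contract_contour(mask: np.ndarray, steps: int) -> np.ndarray:
    """Erode a 2-D mask ``steps`` times with a 3×3 cross element."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    m = np.asarray(mask, dtype=bool)
    if steps == 0:
        return m.copy()
    return ndimage.binary_erosion(m, structure=_CROSS, iterations=steps)


def transfer_roi(roi: DiscROI, dst_geometry: Geometry) -> DiscROI:
    """Map an ROI onto another parallel grid via patient coordinates.

    Each source voxel center is located in patient space (slice position plus
    index × spacing from the in-plane origin) and assigned to the nearest
    destination voxel; duplicates collapse, voxels falling outside the
    destination grid are dropped. Slices correspond by nearest slice position.
    Oblique (non-parallel) resampling is unsupported.
    """
    src = roi.geometry
    if not src.compatible_orientation(dst_geometry):
        raise GeometryError("source and destination stacks must share orientation")

    idx = roi.voxel_indices()
    dst_mask = np.zeros(
        (dst_geometry.n_slices,)
        + _dst_inplane_shape(roi.mask.shape[1:], src, dst_geometry),
        dtype=bool,
    )
    if idx.size:
        src_pos = np.asarray(src.slice_positions)[idx[:, 0]]
        dst_slice = dst_geometry.nearest_slice(src_pos)
        coords = src.inplane_coords(idx[:, 1], idx[:, 2])
        rows, cols = dst_geometry.nearest_inplane_index(coords)
        inb = (
            (rows >= 0)
            & (rows < dst_mask.shape[1])
            & (cols >= 0)
            & (cols < dst_mask.shape[2])
        )
        dst_mask[dst_slice[inb], rows[inb], cols[inb]] = True

    occupied = np.flatnonzero(dst_mask.any(axis=(1, 2)))
    intact = occupied.size == 3 and np.array_equal(occupied, occupied[0] + np.arange(3))
    return DiscROI(
        subject=roi.subject,
        level=roi.level,
        mask=dst_mask,
        geometry=dst_geometry,
        provenance=dict(roi.provenance, transferred_from=src),
        degenerate=not intact,
        strict=False,
    )


def _dst_inplane_shape(
    src_shape: tuple[int, int], src: Geometry, dst: Geometry
) -> tuple[int, int]:
    """In-plane shape covering the source field of view on the dst grid."""
    rows = int(np.ceil(src_shape[0] * src.pixel_spacing[0] / dst.pixel_spacing[0]))
    cols = int(np.ceil(src_shape[1] * src.pixel_spacing[1] / dst.pixel_spacing[1]))
    return rows, cols


def build_disc_roi(
    structural: np.ndarray,
    geometry: Geometry,
    subject: str,
    level: str,
    seed_point: tuple[int, int, int],
    tolerance: float = 0.25,
    contract_steps: int = 1,
    include: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> DiscROI:
    """Segment one disc over three consecutive slices around a seed.

    ``seed_point`` is (slice, row, col) on the middle of the three slices.
    Optional ``include``/``exclude`` boolean volumes model manual strokes:
    include voxels are forced in before contraction, exclude voxels forced
    out. A fully eroded (empty) result is returned flagged degenerate.
    """
    s_mid, r, c = seed_point
    n_slices = structural.shape[0]
    if not 0 <= s_mid < n_slices:
        raise ValueError("seed slice outside the stack")
    if n_slices < 3:
        raise ValueError("stack must have at least three slices")
    lo = int(np.clip(s_mid - 1, 0, n_slices - 3))
    mask = np.zeros(structural.shape, dtype=bool)
    for s in range(lo, lo + 3):
        grown = region_grow(structural[s], (r, c), tolerance)
        if include is not None:
            grown |= include[s]
        if exclude is not None:
            grown &= ~exclude[s]
        eroded = contract_contour(grown, contract_steps)
        if eroded.any():
            labels = measure.label(eroded, connectivity=2)
            lab = labels[r, c]
            if lab == 0:  # seed eroded away: keep the largest remaining piece
                lab = np.argmax(np.bincount(labels.ravel())[1:]) + 1
            eroded = labels == lab
        mask[s] = eroded

    provenance = {
        "seed": tuple(int(v) for v in seed_point),
        "tolerance": tolerance,
        "contract_steps": contract_steps,
    }
    if not all(mask[s].any() for s in range(lo, lo + 3)):
        return DiscROI(
            subject=subject,
            level=level,
            mask=np.zeros_like(mask),
            geometry=geometry,
            provenance=provenance,
            degenerate=True,
        )
    return DiscROI(
        subject=subject,
        level=level,
        mask=mask,
        geometry=geometry,
        slices=(lo, lo + 1, lo + 2),
        provenance=provenance,
    )
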