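"""Five-band anterior→posterior partition of a disc ROI.

The ROI (pooled over its three slices) is projected onto an in-plane
anterior–posterior axis and split into five intervals of equal geometric
length; band 1 is the anterior extreme, band 5 the posterior extreme. When no
axis is supplied it is estimated as the principal second-moment axis of the
pooled ROI, signed so that increasing projection means posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import DiscROI

__all__ = ["SubRegionPartition", "partition_subregions", "N_BANDS"]

N_BANDS = 5


@dataclass(frozen=True)
class SubRegionPartition:
    """Per-voxel band labels 1..5 over a grid (0 outside the ROI)."""

    labels: np.ndarray
    ap_axis: np.ndarray
    counts: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (slice, row, col)")
        if self.counts.shape != (N_BANDS,):
            raise ValueError("counts must have one entry per band")

    def band_mask(self, band: int) -> np.ndarray:
        if not 1 <= band <= N_BANDS:
            raise ValueError(f"band must be 1..{N_BANDS}")
        return self.labels == band


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 0:
        raise ValueError("ROI has zero in-plane extent; no principal axis")
    return eigvecs[:, -1]


def partition_subregions(roi: DiscROI, ap_axis: np.ndarray | None = None) -> SubRegionPartition:
    """Assign each ROI voxel to one of five equal-length AP bands.

    A single axis is estimated from the three-slice pooled ROI and applied to
    every voxel. The projected range [min, max] is cut into five equal-length
    intervals; a projection exactly on an interior edge goes to the
    lower-index band. Sub-region voxel counts are reported so the
    equal-count alternative reading can be audited.
    """
    if roi.degenerate or not roi.mask.any():
        raise ValueError("cannot partition an empty or degenerate ROI")
    idx = roi.voxel_indices()
    coords = roi.geometry.inplane_coords(idx[:, 1], idx[:, 2])

    if ap_axis is None:
        axis = _principal_axis(coords)
    else:
        axis = np.asarray(ap_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("ap_axis must be a nonzero vector")
        axis = axis / norm
    # Sign the axis so increasing projection points posterior.
    posterior = np.asarray(roi.geometry.posterior, dtype=float)
    d = float(axis @ posterior)
    if abs(d) < 1e-12:
        # Axis perpendicular to the posterior direction: orient by grid order.
        d = axis[1] if axis[1] != 0 else axis[0]
    if d < 0:
        axis = -axis

    proj = coords @ axis
    lo, hi = proj.min(), proj.max()
    span = hi - lo
    if span <= 0:
        raise ValueError("ROI has zero extent along the AP axis")
    u = (proj - lo) / span * N_BANDS
    labels_flat = np.clip(np.ceil(u).astype(int), 1, N_BANDS)

    labels = np.zeros(roi.mask.shape, dtype=np.uint8)
    labels[tuple(idx.T)] = labels_flat
    counts = np.bincount(labels_flat, minlength=N_BANDS + 1)[1:]
    edges = lo + span * np.arange(N_BANDS + 1) / N_BANDS
    return SubRegionPartition(labels=labels, ap_axis=axis, counts=counts, edges=edges)
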