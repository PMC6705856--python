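"""Voxel-wise mono-exponential T2 fitting and bright-noise truncation.

The signal model is ``S(t) = S0 * exp(-t / T2)`` fitted per voxel to a
multi-echo magnitude series. Two fit routes are provided:

``loglinear``
    Weighted least squares on ``ln S`` versus echo time, with weights
    proportional to ``S**2`` to counter the variance distortion of the log
    transform. Fast, deterministic, the default.
``nonlinear``
    Levenberg–Marquardt style least-squares refinement of the exponential
    model in the signal domain, initialized from the log-linear solution.

A voxel is invalid when any echo magnitude is non-positive, when the fitted
log-domain slope is non-negative (no decay), or when the fitted T2 exceeds an
optional hard ceiling. Invalid voxels are excluded from all downstream
statistics rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import optimize

from .geometry import Geometry

__all__ = [
    "MultiEchoSeries",
    "T2Map",
    "VoxelFit",
    "fit_t2_voxel",
    "fit_t2_map",
    "truncate_bright_noise",
]

#: Echo times (ms) of the reference multi-echo spin-echo protocol.
DEFAULT_ECHO_TIMES: tuple[float, ...] = (11.1, 22.2, 33.3, 44.4, 55.5, 66.6, 77.7, 88.8)


def _check_echo_times(echo_times: np.ndarray) -> np.ndarray:
    t = np.asarray(echo_times, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("at least 3 echo times are required")
    if t[0] <= 0 or np.any(np.diff(t) <= 0):
        raise ValueError("echo times must be positive and strictly increasing")
    return t


@dataclass(frozen=True)
class MultiEchoSeries:
    """A 4-D magnitude stack (echo × slice × row × col) with its geometry."""

    data: np.ndarray
    echo_times: tuple[float, ...]
    geometry: Geometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError("data must be 4-D (echo, slice, row, col)")
        t = _check_echo_times(np.asarray(self.echo_times))
        if data.shape[0] != t.size:
            raise ValueError("echo axis length must match the echo-time list")
        if data.shape[1] != self.geometry.n_slices:
            raise ValueError("slice axis length must match geometry.slice_positions")
        if np.any(data < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "data", data)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class T2Map:
    """Per-voxel T2 (ms), S0 and validity over a slice stack.

    ``t2``, ``s0`` and ``r2`` are NaN wherever ``valid`` is False; only valid
    voxels participate in any downstream statistic.
    """

    t2: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    r2: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        shapes = {self.t2.shape, self.s0.shape, self.valid.shape, self.r2.shape}
        if len(shapes) != 1:
            raise ValueError("t2, s0, valid and r2 must share one shape")
        if self.t2.ndim != 3:
            raise ValueError("maps must be 3-D (slice, row, col)")
        if self.t2.shape[0] != self.geometry.n_slices:
            raise ValueError("slice axis length must match geometry.slice_positions")
        v = self.valid
        ok = v & np.isfinite(self.t2) & (self.t2 > 0) & np.isfinite(self.s0) & (self.s0 > 0)
        if not np.array_equal(v, ok):
            raise ValueError("valid voxels must have finite T2 > 0 and S0 > 0")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


class VoxelFit(NamedTuple):
    s0: float
    t2: float
    valid: bool
    r2: float


def _loglinear_arrays(
    signals: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized weighted log-linear fit.

    ``signals`` has shape (n_voxels, n_echoes); voxels containing any
    non-positive magnitude come back invalid. Returns (s0, t2, valid, r2).
    """
    n_vox = signals.shape[0]
    s0 = np.full(n_vox, np.nan)
    t2 = np.full(n_vox, np.nan)
    r2 = np.full(n_vox, np.nan)
    valid = np.zeros(n_vox, dtype=bool)

    pos = np.all(signals > 0, axis=1)
    if not pos.any():
        return s0, t2, valid, r2

    s = signals[pos]
    y = np.log(s)
    w = s**2
    wsum = w.sum(axis=1)
    xbar = (w * t).sum(axis=1) / wsum
    ybar = (w * y).sum(axis=1) / wsum
    dx = t[None, :] - xbar[:, None]
    dy = y - ybar[:, None]
    sxx = (w * dx**2).sum(axis=1)
    slope = (w * dx * dy).sum(axis=1) / sxx
    intercept = ybar - slope * xbar

    resid = dy - slope[:, None] * dx
    ss_res = (w * resid**2).sum(axis=1)
    ss_tot = (w * dy**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_pos = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)

    ok = slope < 0
    with np.errstate(divide="ignore", over="ignore"):
        s0_pos = np.where(ok, np.exp(intercept), np.nan)
        t2_pos = np.where(ok, -1.0 / slope, np.nan)

    s0[pos] = s0_pos
    t2[pos] = t2_pos
    r2[pos] = np.where(ok, r2_pos, np.nan)
    valid[pos] = ok
    return s0, t2, valid, r2


def _nonlinear_refine(signal: np.ndarray, t: np.ndarray, s0_init: float, t2_init: float) -> tuple[float, float]:
    def residual(params: np.ndarray) -> np.ndarray:
        s0, t2 = params
        return s0 * np.exp(-t / t2) - signal

    res = optimize.least_squares(
        residual,
        x0=np.array([s0_init, t2_init]),
        bounds=([0.0, 1e-6], [np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return float(res.x[0]), float(res.x[1])


def fit_t2_voxel(
    signal: np.ndarray,
    echo_times: np.ndarray | tuple[float, ...],
    method: str = "loglinear",
    ceiling: float | None = None,
) -> VoxelFit:
    """Fit ``S(t) = S0 exp(-t/T2)`` to one voxel's echo train.

    Parameters
    ----------
    signal:
        Magnitudes at each echo.
    echo_times:
        Strictly increasing echo times (ms), at least 3.
    method:
        ``"loglinear"`` or ``"nonlinear"`` (log-linear initialized refinement).
    ceiling:
        Optional hard T2 ceiling (ms); fits above it are marked invalid.

    Returns
    -------
    VoxelFit
        ``(s0, t2, valid, r2)``; ``r2`` is the weighted R² of the log-linear
        fit in both methods.
    """
    t = _check_echo_times(np.asarray(echo_times))
    s = np.asarray(signal, dtype=float)
    if s.shape != t.shape:
        raise ValueError("signal and echo_times must have the same length")
    if method not in ("loglinear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    if ceiling is not None and ceiling <= 0:
        raise ValueError("ceiling must be positive")

    s0_a, t2_a, valid_a, r2_a = _loglinear_arrays(s[None, :], t)
    s0, t2, valid, r2 = float(s0_a[0]), float(t2_a[0]), bool(valid_a[0]), float(r2_a[0])

    if valid and method == "nonlinear":
        s0, t2 = _nonlinear_refine(s, t, s0, t2)
        if not (np.isfinite(t2) and t2 > 0 and np.isfinite(s0) and s0 > 0):
            valid = False

    if valid and ceiling is not None and t2 > ceiling:
        valid = False
    if not valid:
        return VoxelFit(np.nan, np.nan, False, np.nan)
    return VoxelFit(s0, t2, True, r2)


def fit_t2_map(
    series: MultiEchoSeries,
    mask: np.ndarray | None = None,
    method: str = "loglinear",
    ceiling: float | None = None,
) -> T2Map:
    """Fit the mono-exponential model voxel-by-voxel over a series.

    ``mask``, if given, is a boolean array over the spatial grid restricting
    the fit; voxels outside it are invalid in the output. The log-linear route
    is fully vectorized; the nonlinear route refines each log-linear-valid
    voxel individually.
    """
    if method not in ("loglinear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    if ceiling is not None and ceiling <= 0:
        raise ValueError("ceiling must be positive")
    shape = series.spatial_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask)
        if mask.dtype != bool or mask.shape != shape:
            raise ValueError("mask must be a boolean array matching the spatial grid")

    t = np.asarray(series.echo_times, dtype=float)
    flat = series.data.reshape(series.data.shape[0], -1).T  # (n_vox, n_echo)
    sel = mask.ravel()

    s0 = np.full(sel.size, np.nan)
    t2 = np.full(sel.size, np.nan)
    r2 = np.full(sel.size, np.nan)
    valid = np.zeros(sel.size, dtype=bool)

    s0_m, t2_m, valid_m, r2_m = _loglinear_arrays(flat[sel], t)

    if method == "nonlinear":
        idx = np.flatnonzero(valid_m)
        sig = flat[sel]
        for i in idx:
            s0_i, t2_i = _nonlinear_refine(sig[i], t, s0_m[i], t2_m[i])
            if np.isfinite(t2_i) and t2_i > 0 and np.isfinite(s0_i) and s0_i > 0:
                s0_m[i], t2_m[i] = s0_i, t2_i
            else:
                valid_m[i] = False
                s0_m[i] = t2_m[i] = r2_m[i] = np.nan

    if ceiling is not None:
        over = valid_m & (t2_m > ceiling)
        valid_m[over] = False
        s0_m[over] = t2_m[over] = r2_m[over] = np.nan

    s0[sel], t2[sel], valid[sel], r2[sel] = s0_m, t2_m, valid_m, r2_m
    return T2Map(
        t2=t2.reshape(shape),
        s0=s0.reshape(shape),
        valid=valid.reshape(shape),
        r2=r2.reshape(shape),
        geometry=series.geometry,
    )


def truncate_bright_noise(t2map: T2Map, ceiling: float) -> T2Map:
    """Invalidate voxels whose T2 exceeds ``ceiling`` (ms).

    Removes bright-noise voxels from the valid set; surviving voxels are
    unchanged and the operation is idempotent.
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    over = t2map.valid & (t2map.t2 > ceiling)
    if not over.any():
        return t2map
    t2 = t2map.t2.copy()
    s0 = t2map.s0.copy()
    r2 = t2map.r2.copy()
    valid = t2map.valid & ~over
    t2[over] = s0[over] = r2[over] = np.nan
    return replace(t2map, t2=t2, s0=s0, valid=valid, r2=r2)
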