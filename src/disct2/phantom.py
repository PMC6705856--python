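"""Synthetic multi-echo lumbar disc phantoms with known ground truth.

Discs are in-plane ellipses replicated over three sagittal slices, with a
high-T2 nucleus pulposus (NP) core, a low-T2 annulus fibrosus (AF) ring, a
grade-dependent decline of NP T2 and widening NP/AF blending, an optional
small bright high-intensity zone (HIZ) confined to the posterior annulus,
and Rician magnitude noise (modulus of complex Gaussian noise around the
noise-free signal). Every phantom carries full ground truth — compartment
masks, true T2 values, grade, HIZ flag — so each downstream stage can be
validated without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Geometry
from .t2map import DEFAULT_ECHO_TIMES, MultiEchoSeries

__all__ = [
    "GradeParams",
    "DiscSpec",
    "PhantomSpec",
    "DiscTruth",
    "GroundTruth",
    "SubjectPhantom",
    "PhantomSpecError",
    "build_phantom",
    "build_cohorts",
    "DEFAULT_GRADE_PARAMS",
    "DEFAULT_GRADE_PROBS",
    "LUMBAR_LEVELS",
]

LUMBAR_LEVELS: tuple[str, ...] = ("L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S1")

#: Grade distribution loosely shaped like a degenerative cohort
#: (mode at grade 2, grade 5 rare).
DEFAULT_GRADE_PROBS: tuple[float, ...] = (0.10, 0.45, 0.25, 0.15, 0.05)


class PhantomSpecError(ValueError):
    """Raised when a phantom spec violates one of its invariants."""


@dataclass(frozen=True)
class GradeParams:
    """Compartment parameters for one degeneration grade.

    ``np_radius`` is the normalized elliptical radius of the pure NP core and
    ``blend`` the half-width of the linear NP→AF transition zone, both in
    units of the disc's normalized radius.
    """

    np_t2: float
    af_t2: float
    np_s0: float = 100.0
    af_s0: float = 80.0
    np_radius: float = 0.6
    blend: float = 0.0


#: NP T2 declines with grade while AF stays fixed; NP/AF blending widens.
DEFAULT_GRADE_PARAMS: dict[int, GradeParams] = {
    1: GradeParams(120.0, 45.0, np_radius=0.65, blend=0.05),
    2: GradeParams(100.0, 45.0, np_radius=0.60, blend=0.08),
    3: GradeParams(80.0, 45.0, np_radius=0.55, blend=0.12),
    4: GradeParams(60.0, 45.0, np_radius=0.50, blend=0.16),
    5: GradeParams(50.0, 45.0, np_radius=0.45, blend=0.20),
}


@dataclass(frozen=True)
class DiscSpec:
    """One disc: level label, in-plane ellipse, grade and HIZ assignment.

    ``center`` and ``semi_axes`` are (row, col) in mm; the column axis is the
    anterior–posterior direction under the default geometry. ``np_t2_offset``
    adds per-disc biological variation to the NP T2 of the grade table.
    """

    level: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    grade: int
    hiz: bool = False
    hiz_center: tuple[float, float] | None = None
    np_t2_offset: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]
    discs: tuple[DiscSpec, ...]
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 4.0
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    grade_params: dict[int, GradeParams] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_PARAMS)
    )
    hiz_t2: float = 150.0
    hiz_s0: float = 100.0
    hiz_radius: float = 1.5
    hiz_np_t2_drop: float = 0.0
    noise_sigma: float = 0.0
    background_t2: float = 25.0
    background_s0: float = 3.0
    seed: int = 0
    subject: str = "sub-00"
    cohort: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.echo_times, dtype=float)
        if t.size < 3 or t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise PhantomSpecError(
                "invariant violated: echo times must be positive and strictly increasing"
            )
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise PhantomSpecError("shape must be (slices, rows, cols) with positive sizes")
        grades = sorted(self.grade_params)
        for g in (1, 2, 3):
            gp = self.grade_params.get(g)
            if gp is not None and gp.np_t2 < gp.af_t2:
                raise PhantomSpecError(
                    f"invariant violated: NP T2 must be >= AF T2 for grade {g}"
                )
        gaps = [self.grade_params[g].np_t2 - self.grade_params[g].af_t2 for g in grades]
        if np.any(np.diff(gaps) > 0):
            raise PhantomSpecError(
                "invariant violated: NP/AF T2 parameters must converge monotonically with grade"
            )
        if self.hiz_radius <= 0:
            raise PhantomSpecError("hiz_radius must be positive")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be non-negative")
        for disc in self.discs:
            if disc.grade not in self.grade_params:
                raise PhantomSpecError(f"no grade parameters for grade {disc.grade}")
            if disc.hiz_center is not None:
                self._check_hiz_center(disc)

    def _check_hiz_center(self, disc: DiscSpec) -> None:
        # Posterior fifth of the AP extent = the last of five equal bands.
        r0, c0 = disc.center
        ar, ac = disc.semi_axes
        ap = float(disc.hiz_center[1] - c0)
        si = float(disc.hiz_center[0] - r0)
        if not (0.6 * ac <= ap <= ac) or abs(si) > ar:
            raise PhantomSpecError(
                "invariant violated: HIZ center must lie in the posterior fifth "
                f"of the AP extent of disc {disc.level}"
            )


@dataclass(frozen=True)
class DiscTruth:
    """Ground-truth compartments for one disc."""

    level: str
    grade: int
    hiz: bool
    mask: np.ndarray
    np_mask: np.ndarray
    af_mask: np.ndarray
    hiz_mask: np.ndarray
    true_t2: dict[str, float]
    center: tuple[float, float]

    def __post_init__(self) -> None:
        for name, sub in (("np", self.np_mask), ("af", self.af_mask), ("hiz", self.hiz_mask)):
            if np.any(sub & ~self.mask):
                raise ValueError(f"{name} mask must be a subset of the disc mask")
        if np.any(self.np_mask & self.af_mask) or np.any(self.np_mask & self.hiz_mask) or np.any(
            self.af_mask & self.hiz_mask
        ):
            raise ValueError("NP, AF and HIZ masks must be disjoint")
        if not self.hiz and self.hiz_mask.any():
            raise ValueError("HIZ mask must be empty when the HIZ flag is false")


@dataclass(frozen=True)
class GroundTruth:
    """All per-disc truths plus the structural reference series."""

    discs: tuple[DiscTruth, ...]
    structural: np.ndarray
    geometry: Geometry
    subject: str = "sub-00"
    cohort: str = ""

    def disc(self, level: str) -> DiscTruth:
        for d in self.discs:
            if d.level == level:
                return d
        raise KeyError(level)


@dataclass(frozen=True)
class SubjectPhantom:
    subject: str
    cohort: str
    series: MultiEchoSeries
    truth: GroundTruth


def _render_disc(
    spec: PhantomSpec,
    disc: DiscSpec,
    rr_mm: np.ndarray,
    cc_mm: np.ndarray,
    t2_2d: np.ndarray,
    s0_2d: np.ndarray,
    struct_2d: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    gp = spec.grade_params[disc.grade]
    r0, c0 = disc.center
    ar, ac = disc.semi_axes
    rho = np.sqrt(((rr_mm - r0) / ar) ** 2 + ((cc_mm - c0) / ac) ** 2)
    disc2d = rho <= 1.0
    np2d = rho <= gp.np_radius

    np_t2 = gp.np_t2 + disc.np_t2_offset
    if disc.hiz:
        np_t2 -= spec.hiz_np_t2_drop
    np_t2 = max(np_t2, gp.af_t2)  # degeneration never pushes NP below AF

    t2_2d[disc2d] = gp.af_t2
    s0_2d[disc2d] = gp.af_s0
    struct_2d[disc2d] = 90.0
    if gp.blend > 0:
        zone = disc2d & (rho > gp.np_radius) & (rho < gp.np_radius + gp.blend)
        frac = (rho[zone] - gp.np_radius) / gp.blend
        t2_2d[zone] = np_t2 * (1 - frac) + gp.af_t2 * frac
        s0_2d[zone] = gp.np_s0 * (1 - frac) + gp.af_s0 * frac
        struct_2d[zone] = 110.0 * (1 - frac) + 90.0 * frac
    t2_2d[np2d] = np_t2
    s0_2d[np2d] = gp.np_s0
    struct_2d[np2d] = 110.0
    return disc2d, np2d


def build_phantom(spec: PhantomSpec) -> tuple[MultiEchoSeries, GroundTruth]:
    """Render a phantom spec into a noisy echo stack plus its ground truth.

    The noise-free voxel signal is ``S0 * exp(-t / T2)`` with compartment T2;
    Rician noise of width ``noise_sigma`` is applied per voxel per echo.
    Identical specs (including seed) produce bit-identical output.
    """
    n_slices, n_rows, n_cols = spec.shape
    dr, dc = spec.pixel_spacing
    geometry = Geometry(
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        slice_positions=tuple(i * spec.slice_thickness for i in range(n_slices)),
    )
    rows_mm = np.arange(n_rows) * dr
    cols_mm = np.arange(n_cols) * dc
    rr_mm, cc_mm = np.meshgrid(rows_mm, cols_mm, indexing="ij")

    t2_2d = np.full((n_rows, n_cols), spec.background_t2)
    s0_2d = np.full((n_rows, n_cols), spec.background_s0)
    struct_2d = np.full((n_rows, n_cols), 20.0)

    truths: list[DiscTruth] = []
    occupied = np.zeros((n_rows, n_cols), dtype=bool)
    for disc in spec.discs:
        disc2d, np2d = _render_disc(spec, disc, rr_mm, cc_mm, t2_2d, s0_2d, struct_2d)
        if np.any(disc2d & occupied):
            raise PhantomSpecError(f"disc {disc.level} overlaps another disc")
        occupied |= disc2d

        gp = spec.grade_params[disc.grade]
        mask3d = np.broadcast_to(disc2d, (n_slices, n_rows, n_cols)).copy()
        np3d = np.broadcast_to(np2d, (n_slices, n_rows, n_cols)).copy()
        hiz3d = np.zeros_like(mask3d)
        if disc.hiz:
            hiz3d = _hiz_mask(spec, disc, geometry, rr_mm, cc_mm, disc2d, np2d)
        af3d = mask3d & ~np3d & ~hiz3d

        np_t2 = gp.np_t2 + disc.np_t2_offset - (spec.hiz_np_t2_drop if disc.hiz else 0.0)
        truths.append(
            DiscTruth(
                level=disc.level,
                grade=disc.grade,
                hiz=disc.hiz,
                mask=mask3d,
                np_mask=np3d,
                af_mask=af3d,
                hiz_mask=hiz3d,
                true_t2={
                    "np": max(np_t2, gp.af_t2),
                    "af": gp.af_t2,
                    "hiz": spec.hiz_t2 if disc.hiz else np.nan,
                },
                center=disc.center,
            )
        )

    t2_vol = np.broadcast_to(t2_2d, (n_slices, n_rows, n_cols)).copy()
    s0_vol = np.broadcast_to(s0_2d, (n_slices, n_rows, n_cols)).copy()
    structural = np.broadcast_to(struct_2d, (n_slices, n_rows, n_cols)).copy()
    for truth in truths:
        if truth.hiz_mask.any():
            t2_vol[truth.hiz_mask] = spec.hiz_t2
            s0_vol[truth.hiz_mask] = spec.hiz_s0
            structural[truth.hiz_mask] = 130.0

    t = np.asarray(spec.echo_times, dtype=float)
    clean = s0_vol[None] * np.exp(-t[:, None, None, None] / t2_vol[None])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        re = clean + spec.noise_sigma * rng.standard_normal(clean.shape)
        im = spec.noise_sigma * rng.standard_normal(clean.shape)
        data = np.hypot(re, im)
    else:
        data = clean

    series = MultiEchoSeries(data=data, echo_times=tuple(t), geometry=geometry)
    truth = GroundTruth(
        discs=tuple(truths),
        structural=structural,
        geometry=geometry,
        subject=spec.subject,
        cohort=spec.cohort,
    )
    return series, truth


def _hiz_mask(
    spec: PhantomSpec,
    disc: DiscSpec,
    geometry: Geometry,
    rr_mm: np.ndarray,
    cc_mm: np.ndarray,
    disc2d: np.ndarray,
    np2d: np.ndarray,
) -> np.ndarray:
    """Spherical HIZ in the posterior annulus, never overlapping the NP core."""
    n_slices = geometry.n_slices
    r0, c0 = disc.center
    ar, ac = disc.semi_axes
    if disc.hiz_center is not None:
        hr, hc = disc.hiz_center
    else:
        hr, hc = r0, c0 + 0.8 * ac
    mid = n_slices // 2
    positions = np.asarray(geometry.slice_positions)
    mask = np.zeros((n_slices,) + disc2d.shape, dtype=bool)
    allowed = disc2d & ~np2d
    for s in range(n_slices):
        dz = positions[s] - positions[mid]
        d2 = (rr_mm - hr) ** 2 + (cc_mm - hc) ** 2 + dz**2
        mask[s] = (d2 <= spec.hiz_radius**2) & allowed
    if not mask.any():
        # Radius smaller than the grid: fall back to the nearest annulus voxel.
        d2 = (rr_mm - hr) ** 2 + (cc_mm - hc) ** 2
        d2 = np.where(allowed, d2, np.inf)
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        mask[mid][idx] = True
    return mask


def _default_disc_layout(grid_cols: int = 48) -> list[tuple[str, tuple[float, float]]]:
    c0 = grid_cols / 2.0
    return [(level, (20.0 + 30.0 * k, c0)) for k, level in enumerate(LUMBAR_LEVELS)]


def build_cohorts(
    n_patients: int,
    n_controls: int,
    hiz_rate_patients: float,
    hiz_rate_controls: float,
    seed: int,
    grade_probs: tuple[float, ...] = DEFAULT_GRADE_PROBS,
    noise_sigma: float = 2.0,
    hiz_np_t2_drop: float = 0.0,
    t2_jitter_sd: float = 0.0,
    grade_params: dict[int, GradeParams] | None = None,
    grade_probs_controls: tuple[float, ...] | None = None,
) -> tuple[list[SubjectPhantom], pd.DataFrame]:
    """Simulate patient-like and control-like cohorts of 5-disc subjects.

    Each subject carries the five lumbar discs (L1-L2 … L5-S1) in a single
    sagittal grid. Grades are drawn independently from ``grade_probs`` (used
    for both cohorts unless ``grade_probs_controls`` gives the control-like
    cohort its own distribution); HIZ lesions are assigned only to discs of
    grade >= 3, with per-cohort rates. Returns the subject phantoms plus a
    cohort-table skeleton (one row per disc: subject, cohort, level, grade,
    HIZ flag) to be filled with metrics.

    Per-subject random streams are spawned deterministically from ``seed``.
    """
    if n_patients < 1 or n_controls < 1:
        raise ValueError("cohort sizes must be >= 1")
    for rate in (hiz_rate_patients, hiz_rate_controls):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("HIZ rates must lie in [0, 1]")

    def _check_probs(p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if p.size != 5 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("grade probabilities must be 5 non-negative values summing to 1")
        return p / p.sum()

    probs_by_cohort = {
        "patient": _check_probs(grade_probs),
        "control": _check_probs(
            grade_probs_controls if grade_probs_controls is not None else grade_probs
        ),
    }
    params = dict(grade_params) if grade_params is not None else dict(DEFAULT_GRADE_PARAMS)

    layout = _default_disc_layout()
    roster = [("patient", i, hiz_rate_patients) for i in range(n_patients)] + [
        ("control", i, hiz_rate_controls) for i in range(n_controls)
    ]
    children = np.random.SeedSequence(seed).spawn(len(roster))

    subjects: list[SubjectPhantom] = []
    records: list[dict] = []
    for (cohort, idx, rate), child in zip(roster, children):
        rng = np.random.default_rng(child)
        subject_id = f"{cohort[:3]}-{idx:03d}"
        discs = []
        for level, center in layout:
            grade = int(rng.choice(np.arange(1, 6), p=probs_by_cohort[cohort]))
            hiz = bool(grade >= 3 and rng.random() < rate)
            offset = float(rng.normal(0.0, t2_jitter_sd)) if t2_jitter_sd > 0 else 0.0
            discs.append(
                DiscSpec(
                    level=level,
                    center=center,
                    semi_axes=(5.5, 16.0),
                    grade=grade,
                    hiz=hiz,
                    np_t2_offset=offset,
                )
            )
        spec = PhantomSpec(
            shape=(3, 160, 48),
            discs=tuple(discs),
            grade_params=params,
            noise_sigma=noise_sigma,
            hiz_np_t2_drop=hiz_np_t2_drop,
            seed=int(rng.integers(2**31 - 1)),
            subject=subject_id,
            cohort=cohort,
        )
        series, truth = build_phantom(spec)
        subjects.append(SubjectPhantom(subject_id, cohort, series, truth))
        for d in discs:
            records.append(
                {
                    "subject": subject_id,
                    "cohort": cohort,
                    "level": d.level,
                    "grade": d.grade,
                    "hiz": d.hiz,
                }
            )
    return subjects, pd.DataFrame.from_records(records)
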