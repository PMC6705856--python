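"""Cohort bookkeeping, grade × HIZ summary tables and the scripted study.

``CohortTable`` keeps one record per disc (subject, cohort, level, grade,
HIZ flag, exclusion bookkeeping and metrics); ``summarize_cohort`` rebuilds
the grade-distribution table with No-HIZ / HIZ / All rows and cohort-relative
percentages; ``run_study`` drives the whole pipeline — phantom cohorts, T2
fitting, truncation, segmentation, ROI transfer, sub-region partition,
metrics, group statistics — deterministically from one seed.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import disc_metrics
from .phantom import SubjectPhantom, build_cohorts
from .regions import partition_subregions
from .segment import build_disc_roi, transfer_roi
from .stats import icc_2_1, mann_whitney_u
from .t2map import fit_t2_map, truncate_bright_noise

__all__ = [
    "CohortTable",
    "StudyConfig",
    "StudyResult",
    "summarize_cohort",
    "hiz_prevalence",
    "run_study",
    "round_half_up",
]

log = logging.getLogger(__name__)

GRADES = (1, 2, 3, 4, 5)

_METRIC_COLS = ["mean_t2", "sd_t2", "delta_mu"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching printed-table percentage style."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortTable:
    """One record per disc with cohort metadata, exclusions and metrics.

    ``data`` must at least carry subject / cohort / level / grade / hiz;
    ``excluded`` (bool) and ``exclusion_reason`` are added when absent.
    (subject, level) pairs are unique; excluded discs keep their reason and
    are omitted from every summary.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "cohort", "level", "grade", "hiz"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.data.duplicated(subset=["subject", "level"]).any():
            raise ValueError("(subject, level) pairs must be unique")
        df = self.data.copy()
        if "excluded" not in df.columns:
            df["excluded"] = False
        if "exclusion_reason" not in df.columns:
            df["exclusion_reason"] = ""
        df["excluded"] = df["excluded"].map(lambda v: bool(v) if pd.notna(v) else False)
        df["exclusion_reason"] = df["exclusion_reason"].map(
            lambda v: v if isinstance(v, str) else ""
        )
        bad = df["excluded"] & (df["exclusion_reason"] == "")
        if bad.any():
            raise ValueError("excluded discs must carry a reason")
        self.data = df

    @property
    def included(self) -> pd.DataFrame:
        return self.data[~self.data["excluded"]]

    def accounting(self) -> dict[str, int]:
        """input = summarized + excluded, made explicit."""
        return {
            "input": len(self.data),
            "summarized": int((~self.data["excluded"]).sum()),
            "excluded": int(self.data["excluded"].sum()),
        }


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Grade × HIZ counts and percentages per cohort.

    Rows are (cohort, {No HIZ, HIZ, All}); columns are counts ``g1..g5`` and
    ``total`` plus matching percentages of the cohort's included disc total,
    half-up rounded to one decimal.
    """
    df = table.included
    if df.empty:
        raise ValueError("no discs remain after exclusions")
    rows = []
    for cohort, grp in df.groupby("cohort", sort=True):
        denom = len(grp)
        for row_name, sub in (
            ("No HIZ", grp[~grp["hiz"].astype(bool)]),
            ("HIZ", grp[grp["hiz"].astype(bool)]),
            ("All", grp),
        ):
            counts = {g: int((sub["grade"] == g).sum()) for g in GRADES}
            rec: dict[str, object] = {"cohort": cohort, "row": row_name}
            for g in GRADES:
                rec[f"g{g}"] = counts[g]
                rec[f"g{g}_pct"] = round_half_up(100.0 * counts[g] / denom)
            rec["total"] = len(sub)
            rec["total_pct"] = round_half_up(100.0 * len(sub) / denom)
            rows.append(rec)
    return pd.DataFrame(rows).set_index(["cohort", "row"])


def hiz_prevalence(table: CohortTable) -> dict[str, float]:
    """Per-cohort percentage of subjects with >= 1 HIZ disc (1 decimal)."""
    df = table.data  # prevalence counts subjects, not surviving discs
    out: dict[str, float] = {}
    for cohort, grp in df.groupby("cohort", sort=True):
        n_subjects = grp["subject"].nunique()
        with_hiz = grp.loc[grp["hiz"].astype(bool) & ~grp["excluded"], "subject"].nunique()
        out[cohort] = round_half_up(100.0 * with_hiz / n_subjects)
    return out


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the end-to-end phantom study.

    The default grade distributions are balanced against the HIZ rates so
    that, in expectation, excluding HIZ discs leaves the two cohorts with the
    same grade composition: the patient grade >= 3 mass is the control mass
    scaled by (1 - hiz_rate_controls) / (1 - hiz_rate_patients). The cohort
    difference then rides on HIZ discs (which also carry an NP T2 reduction)
    and is expected to vanish once they are excluded.
    """

    n_patients: int = 25
    n_controls: int = 12
    hiz_rate_patients: float = 0.65
    hiz_rate_controls: float = 0.08
    grade_probs: tuple[float, ...] = (0.0526, 0.3944, 0.3110, 0.2074, 0.0346)
    grade_probs_controls: tuple[float, ...] = (0.08, 0.60, 0.18, 0.12, 0.02)
    noise_sigma: float = 1.5
    hiz_np_t2_drop: float = 35.0
    t2_jitter_sd: float = 4.0
    fit_method: str = "loglinear"
    truncation_ceiling: float = 300.0
    segment_tolerance: float = 0.25
    contract_steps: int = 1
    make_figures: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        payload = json.loads(Path(path).read_text())
        if "grade_probs" in payload:
            payload["grade_probs"] = tuple(payload["grade_probs"])
        return cls(**payload)


@dataclass
class StudyResult:
    table: CohortTable
    summary: pd.DataFrame
    prevalence: dict[str, float]
    comparisons: pd.DataFrame
    reliability: dict[str, object]
    seed: int
    config: StudyConfig = field(repr=False)


def _analyze_subject(subj: SubjectPhantom, config: StudyConfig) -> list[dict]:
    """Fit, segment and measure all five discs of one subject."""
    t2map = fit_t2_map(subj.series, method=config.fit_method)
    t2map = truncate_bright_noise(t2map, config.truncation_ceiling)
    geometry = subj.truth.geometry
    mid = geometry.n_slices // 2
    records = []
    for truth in subj.truth.discs:
        rec: dict[str, object] = {
            "subject": subj.subject,
            "cohort": subj.cohort,
            "level": truth.level,
            "grade": truth.grade,
            "hiz": truth.hiz,
            "excluded": False,
            "exclusion_reason": "",
        }
        seed_vox = (
            mid,
            int(round(truth.center[0] / geometry.pixel_spacing[0])),
            int(round(truth.center[1] / geometry.pixel_spacing[1])),
        )
        try:
            roi = build_disc_roi(
                subj.truth.structural,
                geometry,
                subj.subject,
                truth.level,
                seed_vox,
                tolerance=config.segment_tolerance,
                contract_steps=config.contract_steps,
            )
            if roi.degenerate:
                raise ValueError("segmentation degenerate (ROI emptied)")
            roi = transfer_roi(roi, t2map.geometry)
            if roi.degenerate:
                raise ValueError("ROI lost during geometric transfer")
            partition = partition_subregions(roi)
            m = disc_metrics(t2map, roi, partition)
        except ValueError as exc:
            rec["excluded"] = True
            rec["exclusion_reason"] = f"{truth.level}: {exc}"
            records.append(rec)
            continue
        rec.update(
            mean_t2=m.mean_t2,
            sd_t2=m.sd_t2,
            delta_mu=m.delta_mu,
            n_valid=m.n_valid,
        )
        for i in range(5):
            rec[f"sr{i + 1}_mean"] = m.subregion_mean[i]
            rec[f"sr{i + 1}_sd"] = m.subregion_sd[i]
        records.append(rec)
    return records


def _compare(
    df: pd.DataFrame, metric: str, stratum: str, exclude_hiz: bool
) -> dict | None:
    sub = df[~df["hiz"].astype(bool)] if exclude_hiz else df
    a = sub.loc[sub["cohort"] == "patient", metric].dropna().to_numpy()
    b = sub.loc[sub["cohort"] == "control", metric].dropna().to_numpy()
    if a.size < 2 or b.size < 2:
        return None  # too few discs in a stratum: significance not tested
    res = mann_whitney_u(a, b, mode="auto" if a.size + b.size <= 20 else "normal")
    return {
        "stratum": stratum,
        "metric": metric,
        "hiz_excluded": exclude_hiz,
        "n_patient": int(a.size),
        "n_control": int(b.size),
        "u": res.u,
        "p": res.p,
        "significant": bool(res.p < 0.05),
    }


def _cohort_comparisons(table: CohortTable) -> pd.DataFrame:
    df = table.included
    rows: list[dict] = []
    strata: list[tuple[str, pd.DataFrame]] = [("grade 1-5", df)]
    for g in GRADES:
        strata.append((f"grade {g}", df[df["grade"] == g]))
    strata.append(("grade 1-2", df[df["grade"].isin((1, 2))]))
    strata.append(("grade 3-5", df[df["grade"].isin((3, 4, 5))]))
    for exclude_hiz in (False, True):
        for name, sub in strata:
            for metric in _METRIC_COLS:
                row = _compare(sub, metric, name, exclude_hiz)
                if row is not None:
                    rows.append(row)
        for i in range(1, 6):
            for kind in ("mean", "sd"):
                row = _compare(df, f"sr{i}_{kind}", f"sub-region {i} {kind}", exclude_hiz)
                if row is not None:
                    rows.append(row)
    return pd.DataFrame(rows)


def _segmentation_reliability(
    subjects: list[SubjectPhantom], config: StudyConfig, max_subjects: int = 8
) -> dict[str, object]:
    """ICC(2,1) between two segmentation settings as a rater-pair proxy.

    Rater A uses the study settings; rater B a looser tolerance and one more
    contraction step, mimicking a second observer's outlines.
    """
    means_a: list[float] = []
    means_b: list[float] = []
    for subj in subjects[:max_subjects]:
        t2map = truncate_bright_noise(
            fit_t2_map(subj.series, method=config.fit_method), config.truncation_ceiling
        )
        geometry = subj.truth.geometry
        mid = geometry.n_slices // 2
        for truth in subj.truth.discs:
            seed_vox = (
                mid,
                int(round(truth.center[0] / geometry.pixel_spacing[0])),
                int(round(truth.center[1] / geometry.pixel_spacing[1])),
            )
            pair = []
            for tol, steps in (
                (config.segment_tolerance, config.contract_steps),
                (config.segment_tolerance * 1.2, config.contract_steps + 1),
            ):
                roi = build_disc_roi(
                    subj.truth.structural, geometry, subj.subject, truth.level,
                    seed_vox, tolerance=tol, contract_steps=steps,
                )
                if roi.degenerate:
                    pair = []
                    break
                vals = t2map.t2[roi.mask & t2map.valid]
                if vals.size == 0:
                    pair = []
                    break
                pair.append(float(vals.mean()))
            if pair:
                means_a.append(pair[0])
                means_b.append(pair[1])
    if len(means_a) < 3:
        return {"icc_mean_t2": None, "n_discs": len(means_a)}
    res = icc_2_1(np.column_stack([means_a, means_b]))
    from .stats import interpret_agreement

    return {
        "icc_mean_t2": res.icc,
        "ci95": [res.ci_low, res.ci_high],
        "interpretation": interpret_agreement(res.icc, "cicchetti"),
        "n_discs": len(means_a),
    }


def run_study(
    config: StudyConfig, seed: int, out_dir: str | Path | None = None
) -> StudyResult:
    """Run the full phantom study and optionally write its result bundle.

    Outputs (when ``out_dir`` is given): ``metrics.csv``, ``summary_table2.csv``,
    ``comparisons.csv``, ``reliability.json``, ``run_log.json`` and, when
    enabled, ``figures/``. Deterministic for a fixed (config, seed).
    """
    subjects, skeleton = build_cohorts(
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        hiz_rate_patients=config.hiz_rate_patients,
        hiz_rate_controls=config.hiz_rate_controls,
        seed=seed,
        grade_probs=config.grade_probs,
        grade_probs_controls=config.grade_probs_controls,
        noise_sigma=config.noise_sigma,
        hiz_np_t2_drop=config.hiz_np_t2_drop,
        t2_jitter_sd=config.t2_jitter_sd,
    )
    records: list[dict] = []
    for subj in subjects:
        try:
            records.extend(_analyze_subject(subj, config))
        except Exception as exc:  # pragma: no cover - stage failure surface
            raise RuntimeError(f"analysis failed for subject {subj.subject}: {exc}") from exc

    table = CohortTable(pd.DataFrame.from_records(records))
    if len(table.data) != len(skeleton):
        raise RuntimeError("record accounting mismatch between skeleton and analysis")
    summary = summarize_cohort(table)
    prevalence = hiz_prevalence(table)
    comparisons = _cohort_comparisons(table)
    reliability = _segmentation_reliability(subjects, config)

    result = StudyResult(
        table=table,
        summary=summary,
        prevalence=prevalence,
        comparisons=comparisons,
        reliability=reliability,
        seed=seed,
        config=config,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.data.to_csv(out_dir / "metrics.csv", index=False)
    result.summary.to_csv(out_dir / "summary_table2.csv")
    result.comparisons.to_csv(out_dir / "comparisons.csv", index=False)
    (out_dir / "reliability.json").write_text(json.dumps(result.reliability, indent=2))
    run_log = {
        "package": "disct2",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": result.seed,
        "config": asdict(result.config),
        "prevalence": result.prevalence,
        "accounting": result.table.accounting(),
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    if result.config.make_figures:
        _make_figures(result.table, out_dir / "figures")


def _make_figures(table: CohortTable, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    df = table.included.dropna(subset=_METRIC_COLS)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, metric in zip(axes, _METRIC_COLS):
        data, labels = [], []
        for g in GRADES:
            for cohort in ("patient", "control"):
                vals = df.loc[(df["grade"] == g) & (df["cohort"] == cohort), metric]
                data.append(vals.to_numpy())
                labels.append(f"{g}\n{cohort[:3]}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(metric)
        ax.set_xlabel("Pfirrmann grade / cohort")
    fig.tight_layout()
    fig.savefig(fig_dir / "metrics_by_grade.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(1, 6)
    for cohort, color in (("patient", "tab:red"), ("control", "tab:blue")):
        sub = df[df["cohort"] == cohort]
        means = np.array([sub[f"sr{i}_mean"].mean() for i in xs])
        sds = np.array([sub[f"sr{i}_mean"].std() for i in xs])
        ax.fill_between(xs, means - sds, means + sds, alpha=0.3, color=color)
        ax.plot(xs, means, color=color, label=cohort)
    ax.set_xlabel("sub-region (1 anterior .. 5 posterior)")
    ax.set_ylabel("mean T2 (ms)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "subregion_patches.png", dpi=100)
    plt.close(fig)
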