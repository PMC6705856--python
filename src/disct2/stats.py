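"""Group-comparison and reliability statistics.

Implements the study's statistical toolkit from first principles so each
routine can be checked against independent oracles: a Mann-Whitney U test
(exact enumeration for small samples, tie-corrected normal approximation
otherwise), unweighted Cohen's kappa, ICC(2,1) (two-way random effects,
absolute agreement, single measure) with an F-based 95% CI, and the
Landis–Koch / Cicchetti interpretation bands.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "MannWhitneyResult",
    "ICCResult",
    "mann_whitney_u",
    "cohens_kappa",
    "icc_2_1",
    "interpret_agreement",
]


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    mode: str


class ICCResult(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float


_EXACT_LIMIT = 20  # combined size up to which full enumeration is feasible


def mann_whitney_u(a, b, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates the permutation distribution of U over all
    C(n, n_a) group assignments of the pooled midranks (ties handled
    exactly); it requires ``n_a + n_b <= 20``. ``mode="normal"`` uses the
    tie-corrected Gaussian approximation with a 0.5 continuity correction.
    ``mode="auto"`` picks exact when feasible.

    Returns the U statistic of sample ``a`` and the two-sided p-value.
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    if mode == "auto":
        mode = "exact" if n1 + n2 <= _EXACT_LIMIT else "normal"

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if mode == "exact":
        if n1 + n2 > _EXACT_LIMIT:
            raise ValueError(f"exact mode supports n_a + n_b <= {_EXACT_LIMIT}")
        p = _exact_p(ranks, n1, u)
    else:
        p = _normal_p(pooled, n1, n2, u)
    return MannWhitneyResult(u=u, p=min(p, 1.0), mode=mode)


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating group assignments of the midranks.

    Doubled ranks are integers even under ties, so comparisons are exact.
    """
    ranks2 = np.rint(2.0 * ranks).astype(np.int64)
    offset = n1 * (n1 + 1)  # doubled rank-sum offset
    u2_obs = int(round(2.0 * u_obs))
    total = comb(ranks2.size, n1)
    n_le = n_ge = 0
    for idx in combinations(range(ranks2.size), n1):
        u2 = int(ranks2[list(idx)].sum()) - offset
        if u2 <= u2_obs:
            n_le += 1
        if u2 >= u2_obs:
            n_ge += 1
    return 2.0 * min(n_le, n_ge) / total


def _normal_p(pooled: np.ndarray, n1: int, n2: int, u: float) -> float:
    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied
        return 1.0
    z = (abs(u - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * sps.norm.sf(z))


def cohens_kappa(r1, r2) -> float:
    """Unweighted Cohen's kappa for two raters' ordinal ratings.

    Returns NaN (undefined) when expected agreement is 1, i.e. both raters
    are constant and identical.
    """
    a = np.asarray(r1).ravel()
    b = np.asarray(r2).ravel()
    if a.size != b.size:
        raise ValueError("ratings must have equal length")
    if a.size < 2:
        raise ValueError("at least 2 rated items are required")
    cats, ai = np.unique(np.concatenate([a, b]), return_inverse=True)
    if cats.size < 2:
        return np.nan  # a single category overall: p_e = 1, kappa undefined
    ia, ib = ai[: a.size], ai[a.size :]
    table = np.zeros((cats.size, cats.size))
    np.add.at(table, (ia, ib), 1.0)
    table /= a.size
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if np.isclose(p_e, 1.0):
        return np.nan
    return (p_o - p_e) / (1.0 - p_e)


def icc_2_1(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (items × raters) array without missing values. The
    coefficient is computed from the two-way ANOVA mean squares,

        (MSR - MSE) / (MSR + (k-1)·MSE + k·(MSC - MSE)/n),

    with the standard F-based (McGraw & Wong) 95% confidence interval.
    Returns NaN bounds when the between-item variance is zero (undefined).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (items >= 2) x (raters >= 2)")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing ratings must be dropped before calling")
    n, k = x.shape

    grand = x.mean()
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    ss_rows = k * ((row_mean - grand) ** 2).sum()
    ss_cols = n * ((col_mean - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(msr, 0.0) or np.isclose(denom, 0.0):
        return ICCResult(np.nan, np.nan, np.nan)
    icc = (msr - mse) / denom

    if np.isclose(mse, 0.0) and np.isclose(msc, mse):
        return ICCResult(icc, icc, icc)  # perfect agreement, zero-width CI

    alpha = 0.05
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return ICCResult(icc, icc, icc)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(float(icc), float(lo), float(hi))


# Bands are right-closed at the printed lower-band upper edges; values in the
# printed gaps (e.g. 0.205) fall to the higher band.
_LANDIS_KOCH = ((0.2, "slight"), (0.4, "fair"), (0.6, "moderate"), (0.8, "substantial"))
_CICCHETTI_EXCELLENT = 0.74


def interpret_agreement(value: float, scale: str) -> str:
    """Map an agreement coefficient to its verbal band.

    ``scale="landis_koch"`` (for kappa): slight <= 0.2 < fair <= 0.4 <
    moderate <= 0.6 < substantial <= 0.8 < almost perfect.
    ``scale="cicchetti"`` (for ICC): poor < 0.40 <= fair < 0.60 <= good
    <= 0.74 < excellent.
    """
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if scale == "landis_koch":
        for edge, label in _LANDIS_KOCH:
            if value <= edge:
                return label
        return "almost perfect"
    if scale == "cicchetti":
        if value < 0.40:
            return "poor"
        if value < 0.60:
            return "fair"
        if value <= _CICCHETTI_EXCELLENT:
            return "good"
        return "excellent"
    raise ValueError(f"unknown scale {scale!r}")
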