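"""Per-disc T2 metrics: mean, SD and the two-Gaussian peak separation Δμ.

The "histogram" analysis operates directly on the empirical distribution of
valid T2 values (no binning): a two-component Gaussian mixture is fitted by
expectation–maximization and the peak separation Δμ = μ2 − μ1 quantifies the
remaining distinction between the low-T2 annulus and high-T2 nucleus
populations. EM is deterministic through a fixed quantile-based
initialization (means at the 25th/75th percentiles, equal weights, SDs at
half the sample SD); optional seeded jittered restarts are available for
difficult samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import N_BANDS, SubRegionPartition
from .segment import DiscROI
from .t2map import T2Map

__all__ = [
    "GaussianMixtureFit",
    "DiscMetrics",
    "roi_mean_sd",
    "fit_two_gaussians",
    "disc_metrics",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GaussianMixtureFit:
    """A converged (or iteration-capped) two-component Gaussian fit.

    Components are sorted so ``mu1 <= mu2``; ``delta_mu = mu2 - mu1 >= 0``.
    ``loglik_path`` records the log-likelihood after every EM iteration and is
    non-decreasing by construction.
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    pi1: float
    pi2: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.pi1 < 1.0 and 0.0 < self.pi2 < 1.0):
            raise ValueError("mixing weights must lie in (0, 1)")
        if abs(self.pi1 + self.pi2 - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component SDs must be positive")
        if self.mu1 > self.mu2:
            raise ValueError("components must be sorted by mean")

    @property
    def delta_mu(self) -> float:
        return self.mu2 - self.mu1


@dataclass(frozen=True)
class DiscMetrics:
    """Whole-disc and per-sub-region T2 statistics for one disc.

    Sub-region entries are NaN (never zero) when a band holds fewer valid
    voxels than the statistic needs; ``delta_mu`` is NaN when the mixture fit
    is not applicable (too few values or zero variance).
    """

    subject: str
    level: str
    mean_t2: float
    sd_t2: float
    delta_mu: float
    n_valid: int
    subregion_mean: tuple[float, ...]
    subregion_sd: tuple[float, ...]
    subregion_n: tuple[int, ...]
    gmm: GaussianMixtureFit | None = None


def roi_mean_sd(t2map: T2Map, voxels: np.ndarray | DiscROI) -> tuple[float, float, int]:
    """Mean and sample SD of valid T2 values inside a voxel set.

    Values are pooled over all slices of the set. SD uses the n−1
    denominator and is NaN (flagged undefined) when fewer than two valid
    voxels remain.
    """
    mask = voxels.mask if isinstance(voxels, DiscROI) else np.asarray(voxels, dtype=bool)
    if mask.shape != t2map.t2.shape:
        raise ValueError("voxel set must match the map grid")
    if not mask.any():
        raise ValueError("voxel set is empty")
    sel = mask & t2map.valid
    n = int(sel.sum())
    if n == 0:
        return np.nan, np.nan, 0
    vals = t2map.t2[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n >= 2 else np.nan
    return mean, sd, n


def _em_loglik(x: np.ndarray, params: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-likelihood and responsibilities for params (mu1, mu2, s1, s2, pi1)."""
    mu = params[0:2]
    sigma = params[2:4]
    pi = np.array([params[4], 1.0 - params[4]])
    logp = (
        np.log(pi)[None, :]
        - np.log(sigma)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
    )
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    resp = np.exp(logp - lse[:, None])
    return float(lse.sum()), resp


def fit_two_gaussians(
    values: np.ndarray,
    init_policy: str = "quantile",
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 0,
    seed: int | None = None,
) -> GaussianMixtureFit:
    """Fit a two-component Gaussian mixture to a T2 sample by EM.

    Parameters
    ----------
    values:
        At least 10 finite values with nonzero variance.
    init_policy:
        ``"quantile"`` (the deterministic default) starts the means at the
        25th/75th percentiles with equal weights and SDs of half the sample SD.
    tol:
        Convergence threshold on the per-observation log-likelihood increment.
    max_iter:
        Iteration cap; hitting it leaves ``converged`` False.
    n_restarts, seed:
        Optional jittered re-initializations; the best-likelihood fit wins.

    Raises
    ------
    ValueError
        On fewer than 10 values, non-finite input, or a zero-variance sample.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("mixture fit requires at least 10 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    sample_sd = x.std()
    if sample_sd == 0:
        raise ValueError("zero-variance sample: mixture is degenerate")
    if init_policy != "quantile":
        raise ValueError(f"unknown init_policy {init_policy!r}")

    q25, q75 = np.percentile(x, [25.0, 75.0])
    if q75 <= q25:
        q25, q75 = x.mean() - 0.5 * sample_sd, x.mean() + 0.5 * sample_sd
    base = np.array([q25, q75, sample_sd / 2.0, sample_sd / 2.0, 0.5])

    inits = [base]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            jit = base.copy()
            jit[0:2] += rng.normal(0.0, 0.25 * sample_sd, size=2)
            jit[0:2] = np.sort(jit[0:2])
            inits.append(jit)

    # Variance floor relative to the data range keeps EM finite on samples
    # concentrated at a handful of points (e.g. noise-free two-compartment data).
    floor = max(1e-3 * float(np.ptp(x)), 1e-9)
    best: GaussianMixtureFit | None = None
    for init in inits:
        fit = _run_em(x, init, tol, max_iter, floor)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def _run_em(
    x: np.ndarray, init: np.ndarray, tol: float, max_iter: int, floor: float
) -> GaussianMixtureFit:
    params = init.copy()
    params[2:4] = np.maximum(params[2:4], floor)
    path: list[float] = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, resp = _em_loglik(x, params)
        if path and ll < path[-1] - 1e-7 * max(1.0, abs(path[-1])):
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        path.append(ll)
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, floor**2))
        pi1 = float(np.clip(nk[0] / x.size, 1e-9, 1.0 - 1e-9))
        params = np.array([mu[0], mu[1], sigma[0], sigma[1], pi1])
        # per-observation increment: makes convergence invariant to sample
        # duplication (the trajectory itself already is)
        if (ll - ll_prev) / x.size < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll

    ll_final, _ = _em_loglik(x, params)
    mu1, mu2, s1, s2, pi1 = params
    if mu1 > mu2:
        mu1, mu2, s1, s2, pi1 = mu2, mu1, s2, s1, 1.0 - pi1
    return GaussianMixtureFit(
        mu1=float(mu1),
        mu2=float(mu2),
        sigma1=float(s1),
        sigma2=float(s2),
        pi1=float(pi1),
        pi2=float(1.0 - pi1),
        loglik=ll_final,
        converged=converged,
        n_iter=n_iter,
        loglik_path=tuple(path),
    )


def disc_metrics(
    t2map: T2Map, roi: DiscROI, partition: SubRegionPartition
) -> DiscMetrics:
    """Assemble whole-ROI mean/SD/Δμ and per-sub-region mean/SD for a disc.

    Δμ is computed on the whole ROI only — the annulus/nucleus separation is
    a whole-disc concept. Sub-region statistics come back NaN for bands with
    no valid voxels.
    """
    if partition.labels.shape != t2map.t2.shape or roi.mask.shape != t2map.t2.shape:
        raise ValueError("map, ROI and partition must share one grid")
    if np.any((partition.labels > 0) != roi.mask):
        raise ValueError("partition labels must cover exactly the ROI")

    mean, sd, n = roi_mean_sd(t2map, roi)
    gmm: GaussianMixtureFit | None = None
    delta = np.nan
    sel = roi.mask & t2map.valid
    vals = t2map.t2[sel]
    if vals.size >= 10 and vals.std() > 0:
        gmm = fit_two_gaussians(vals)
        delta = gmm.delta_mu

    sr_mean, sr_sd, sr_n = [], [], []
    for band in range(1, N_BANDS + 1):
        bsel = (partition.labels == band) & t2map.valid
        bn = int(bsel.sum())
        sr_n.append(bn)
        if bn == 0:
            sr_mean.append(np.nan)
            sr_sd.append(np.nan)
            continue
        bvals = t2map.t2[bsel]
        sr_mean.append(float(bvals.mean()))
        sr_sd.append(float(bvals.std(ddof=1)) if bn >= 2 else np.nan)

    return DiscMetrics(
        subject=roi.subject,
        level=roi.level,
        mean_t2=mean,
        sd_t2=sd,
        delta_mu=delta,
        n_valid=n,
        subregion_mean=tuple(sr_mean),
        subregion_sd=tuple(sr_sd),
        subregion_n=tuple(sr_n),
        gmm=gmm,
    )
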