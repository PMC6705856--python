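"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately takes a different computational route than the
package implementation it checks: exhaustive grids instead of optimizers,
pairwise-comparison counting instead of rank algebra, direct ANOVA sums
instead of closed forms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def grid_search_t2(signal: np.ndarray, echo_times: np.ndarray,
                   t2_grid: np.ndarray) -> tuple[float, float]:
    """Exhaustive mono-exponential fit: for each candidate T2 the optimal S0
    is closed-form, so SSE(T2) = sum(s^2) - (s.e)^2 / (e.e). Returns the
    (s0, t2) minimizing SSE over the grid."""
    s = np.asarray(signal, dtype=float)
    t = np.asarray(echo_times, dtype=float)
    e = np.exp(-t[None, :] / t2_grid[:, None])  # (grid, echo)
    se = e @ s
    ee = (e * e).sum(axis=1)
    sse = (s**2).sum() - se**2 / ee
    k = int(np.argmin(sse))
    return float(se[k] / ee[k]), float(t2_grid[k])


def grid_search_t2_many(signals: np.ndarray, echo_times: np.ndarray,
                        t2_grid: np.ndarray) -> np.ndarray:
    """Vectorized grid search over many voxels; returns best T2 per voxel."""
    t = np.asarray(echo_times, dtype=float)
    e = np.exp(-t[None, :] / t2_grid[:, None])
    se = signals @ e.T                      # (vox, grid)
    ee = (e * e).sum(axis=1)                # (grid,)
    sse = (signals**2).sum(axis=1)[:, None] - se**2 / ee[None, :]
    return t2_grid[np.argmin(sse, axis=1)]


def mann_whitney_exact_bruteforce(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney from pairwise comparisons.

    U is counted directly as #(a_i > b_j) + 0.5 #(a_i == b_j); the null
    distribution enumerates every split of the pooled sample.
    """
    def u_stat(x: np.ndarray, y: np.ndarray) -> float:
        gt = (x[:, None] > y[None, :]).sum()
        eq = (x[:, None] == y[None, :]).sum()
        return float(gt) + 0.5 * float(eq)

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = pooled.size
    u_obs = u_stat(a, b)
    n_le = n_ge = total = 0
    for idx in combinations(range(n), a.size):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        total += 1
        n_le += u <= u_obs + 1e-12
        n_ge += u >= u_obs - 1e-12
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / total)


def gmm_loglik(x: np.ndarray, mu1: float, mu2: float, s1: float, s2: float,
               pi1: float) -> float:
    """Direct two-component Gaussian log-likelihood."""
    from scipy.stats import norm

    dens = pi1 * norm.pdf(x, mu1, s1) + (1 - pi1) * norm.pdf(x, mu2, s2)
    return float(np.log(dens).sum())


def gmm_grid_search(x: np.ndarray, mu1_grid, mu2_grid, s1_grid, s2_grid,
                    pi_grid) -> tuple[dict, float]:
    """Best two-Gaussian parameters over a full parameter grid."""
    best, best_ll = None, -np.inf
    for mu1 in mu1_grid:
        for mu2 in mu2_grid:
            for s1 in s1_grid:
                for s2 in s2_grid:
                    for pi1 in pi_grid:
                        ll = gmm_loglik(x, mu1, mu2, s1, s2, pi1)
                        if ll > best_ll:
                            best_ll = ll
                            best = {"mu1": mu1, "mu2": mu2, "s1": s1, "s2": s2, "pi1": pi1}
    return best, best_ll


def icc_2_1_anova(x: np.ndarray) -> float:
    """ICC(2,1) from an explicitly summed two-way ANOVA decomposition."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ms_rows = sum(k * (row.mean() - grand) ** 2 for row in x) / (n - 1)
    ms_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (ms_rows - mse) / (ms_rows + (k - 1) * mse + k * (ms_cols - mse) / n)


def kappa_from_table(r1, r2) -> float:
    """Cohen's kappa via explicit double loops over the contingency table."""
    cats = sorted(set(r1) | set(r2))
    n = len(r1)
    obs = sum(1 for a, b in zip(r1, r2) if a == b) / n
    exp = 0.0
    for c in cats:
        p1 = sum(1 for a in r1 if a == c) / n
        p2 = sum(1 for b in r2 if b == c) / n
        exp += p1 * p2
    return (obs - exp) / (1 - exp)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
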