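"""Rhythm statistics: circular tests, a JTK_CYCLE-style rank test, Grubbs.

Phase times (activity onsets/offsets, expression peaks) are treated as
points on the 24-h circle.  The Rayleigh test asks whether a single sample
is concentrated (mean resultant length rho against a uniform null); the
two-sample Watson U2 test compares two circular distributions through the
squared discrepancy of their empirical CDFs around the circle, with a
seeded permutation null by default.

The JTK-style rhythmicity test matches a sampled time course against
phased cosine reference orderings: for every (period, lag) combination it
computes Kendall's S between data and reference, gets a per-combination
p-value from the exact null distribution of S (Harding's convolution of
the Jonckheere-Terpstra statistic over the reference tie groups -- exact
for tie-free data at any sample size), and Bonferroni-corrects the minimum
over the grid.  A seeded permutation null replaces the exact one when the
data themselves contain ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "hours_to_radians",
    "circular_mean",
    "RayleighResult",
    "rayleigh_test",
    "watson_u2",
    "JTKResult",
    "jtk_cycle",
    "grubbs_test",
    "grubbs_outliers",
    "kendall_s",
    "harding_null_sf",
]


def hours_to_radians(t_h, period_h: float = 24.0):
    """Map clock hours to angles: ``2 pi (t mod period) / period``."""
    if period_h <= 0:
        raise ValueError("period must be > 0")
    return 2.0 * np.pi * np.mod(np.asarray(t_h, dtype=float), period_h) / period_h


def circular_mean(angles_rad) -> float:
    """Mean direction in [0, 2 pi)."""
    a = np.asarray(angles_rad, dtype=float)
    return float(np.mod(math.atan2(np.sin(a).sum(), np.cos(a).sum()), 2.0 * np.pi))


@dataclass
class RayleighResult:
    mean_angle_rad: float
    rho: float
    p_value: float
    z: float
    n: int


def rayleigh_test(angles_rad) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    rho is the mean resultant length; Z = n rho^2; the p-value uses the
    standard exponential-series approximation, accurate over the whole
    range of n.
    """
    a = np.asarray(angles_rad, dtype=float)
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 angles")
    C, S = np.cos(a).sum(), np.sin(a).sum()
    R = math.hypot(C, S)
    rho = R / n
    z = n * rho**2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return RayleighResult(circular_mean(a), rho, p, z, n)


# ---------------------------------------------------------------------------
# two-sample Watson U2


def _watson_u2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Watson U2 from the pooled-sample ECDF differences.

    Ties across samples are handled by evaluating both ECDFs after each
    tied block (midrank-equivalent), which keeps the statistic symmetric
    in the two samples.
    """
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.zeros(n, dtype=bool), np.ones(m, dtype=bool)])
    order = np.argsort(pooled, kind="mergesort")
    z = pooled[order]
    lab = labels[order]
    # counts of each sample up to and including position k
    ca = np.cumsum(~lab) / n
    cb = np.cumsum(lab) / m
    # collapse tied blocks: evaluate at the end of each block, weighted by size
    block_end = np.r_[np.nonzero(np.diff(z) != 0)[0], len(z) - 1]
    sizes = np.diff(np.r_[-1, block_end])
    d = ca[block_end] - cb[block_end]
    N = n + m
    dbar = np.sum(d * sizes) / N
    u2 = (n * m / N**2) * np.sum(sizes * (d - dbar) ** 2)
    return float(u2)


def watson_u2(
    sample_a,
    sample_b,
    n_permutations: int = 10000,
    seed: int = 0,
    method: str = "permutation",
) -> tuple[float, float]:
    """Two-sample Watson U2 test on the circle.

    Returns ``(U2, p)``.  The default p-value is a seeded label-permutation
    estimate ``(1 + #{U2* >= U2}) / (B + 1)``; ``method="asymptotic"``
    instead uses the large-sample tail approximation
    ``p = 2 exp(-2 pi^2 U2)`` (first term of the series), adequate for
    p < 0.2 cross-checks.
    """
    a = np.mod(np.asarray(sample_a, dtype=float), 2.0 * np.pi)
    b = np.mod(np.asarray(sample_b, dtype=float), 2.0 * np.pi)
    if len(a) < 4 or len(b) < 4:
        raise ValueError("need at least 4 angles per sample")
    u2 = _watson_u2_stat(a, b)
    if method == "asymptotic":
        p = min(1.0, 2.0 * math.exp(-2.0 * math.pi**2 * u2))
        return u2, p
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'asymptotic'")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n = len(a)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _watson_u2_stat(perm[:n], perm[n:]) >= u2 - 1e-12:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return u2, p


# ---------------------------------------------------------------------------
# Kendall S and Harding's exact null


def kendall_s(x: np.ndarray, ref: np.ndarray) -> int:
    """Kendall's S = #concordant - #discordant pairs between ``x`` and a
    reference ordering ``ref`` (pairs tied in either vector contribute 0)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    dx = np.sign(x[:, None] - x[None, :])
    dr = np.sign(ref[:, None] - ref[None, :])
    return int(np.sum(np.triu(dx * dr, k=1)))


def _kendall_tau_b(x: np.ndarray, ref: np.ndarray) -> float:
    """Tie-corrected Kendall tau-b consistent with :func:`kendall_s`."""
    n = len(x)
    s = kendall_s(x, ref)
    n0 = n * (n - 1) // 2

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return int(np.sum(counts * (counts - 1) // 2))

    d1 = n0 - tie_term(x)
    d2 = n0 - tie_term(ref)
    if d1 == 0 or d2 == 0:
        return 0.0
    return s / math.sqrt(d1 * d2)


def _gaussian_binomial_coeffs(m: int, n: int) -> np.ndarray:
    """Coefficients of the Gaussian binomial [m+n choose n]_q: the exact
    null distribution (up to normalisation) of the Mann-Whitney U count
    for group sizes m and n.  Computed as prod_j (1-q^(m+j))/(1-q^j)."""
    deg = m * n
    poly = np.zeros(deg + 1, dtype=float)
    poly[0] = 1.0
    top = 0
    for j in range(1, n + 1):
        # multiply by (1 - q^(m+j))
        top_new = min(deg, top + m + j)
        nxt = poly.copy()
        if m + j <= deg:
            nxt[m + j :] -= poly[: deg + 1 - (m + j)]
        poly = nxt
        # divide by (1 - q^j): cumulative sum with stride j
        for i in range(j, deg + 1):
            poly[i] += poly[i - j]
        top = top_new
    return poly


def harding_null_sf(group_sizes: Sequence[int]) -> np.ndarray:
    """Exact null distribution of the Jonckheere-Terpstra statistic
    JT = sum of pairwise Mann-Whitney counts over ordered groups, for
    tie-free data, via Harding's convolution: the probability-generating
    function is the product of Gaussian binomials [N_i choose n_i]_q.

    Returns the probability mass function over JT = 0..max.
    """
    sizes = [int(s) for s in group_sizes if s > 0]
    pmf = np.array([1.0])
    cum = sizes[0]
    for ni in sizes[1:]:
        g = _gaussian_binomial_coeffs(cum, ni)
        g = g / g.sum()
        pmf = np.convolve(pmf, g)
        cum += ni
    return pmf


@dataclass
class JTKResult:
    p_value: float
    best_period_h: float
    best_lag_h: float
    tau_statistic: float
    n_combinations: int


def _cosine_reference(times_h: np.ndarray, period_h: float, lag_h: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (times_h - lag_h) / period_h)


def jtk_cycle(
    times_zt,
    values,
    period_grid_h: Sequence[float] = (24.0,),
    lag_step_h: float | None = None,
    seed: int = 0,
    n_permutations: int = 10000,
    method: str = "auto",
) -> JTKResult:
    """JTK_CYCLE-style nonparametric rhythmicity test.

    ``times_zt`` may repeat (replicates).  For each (period, lag) the data
    are correlated with a cosine reference peaking at the lag; the reported
    p-value is the per-combination minimum Bonferroni-corrected by the
    number of combinations.  ``method``: "exact" (Harding null; requires
    tie-free values), "permutation" (seeded), or "auto" (exact when the
    values are tie-free, else permutation).
    """
    t = np.asarray(times_zt, dtype=float)
    x = np.asarray(values, dtype=float)
    if len(t) != len(x):
        raise ValueError("times and values length mismatch")
    if len(np.unique(t)) < 4:
        raise ValueError("need >= 4 distinct time points")
    if np.all(x == x[0]):
        return JTKResult(1.0, float(period_grid_h[0]), 0.0, 0.0, 0)
    if lag_step_h is None:
        ut = np.unique(t)
        lag_step_h = float(np.min(np.diff(ut)))

    tie_free = len(np.unique(x)) == len(x)
    if method == "auto":
        method = "exact" if tie_free else "permutation"
    if method == "exact" and not tie_free:
        raise ValueError("exact null requires tie-free values; use permutation")

    combos = []
    for P in period_grid_h:
        lags = np.arange(0.0, P, lag_step_h)
        for lag in lags:
            combos.append((float(P), float(lag)))

    rng = np.random.default_rng(seed)
    best = None  # (p, period, lag, tau)
    for P, lag in combos:
        ref = _cosine_reference(t, P, lag)
        s_obs = kendall_s(x, ref)
        tau = _kendall_tau_b(x, ref)
        if method == "exact":
            p = _exact_p_one_sided(x, ref, s_obs)
        else:
            count = 0
            for _ in range(n_permutations):
                if kendall_s(rng.permutation(x), ref) >= s_obs:
                    count += 1
            p = (1.0 + count) / (n_permutations + 1.0)
        if best is None or p < best[0] or (p == best[0] and tau > best[3]):
            best = (p, P, lag, tau)
    p_adj = min(1.0, best[0] * len(combos))
    return JTKResult(p_adj, best[1], best[2], best[3], len(combos))


def _exact_p_one_sided(x: np.ndarray, ref: np.ndarray, s_obs: int) -> float:
    """P(S >= s_obs) under random assignment of tie-free values to the
    reference's tie groups, via the Harding JT null."""
    order = np.argsort(ref, kind="mergesort")
    _, sizes = np.unique(ref[order], return_counts=True)
    pmf = harding_null_sf(sizes)
    s_max = int(sum(
        sizes[i] * sizes[j] for i in range(len(sizes)) for j in range(i + 1, len(sizes))
    ))
    # S = 2 JT - s_max  =>  JT >= (s_obs + s_max) / 2
    jt_min = math.ceil((s_obs + s_max) / 2.0 - 1e-9)
    jt_min = max(0, min(jt_min, len(pmf)))
    return float(pmf[jt_min:].sum())


# ---------------------------------------------------------------------------
# Grubbs outlier test


def _grubbs_critical(n: int, alpha: float) -> float:
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values, alpha: float = 0.05) -> int | None:
    """Single-pass Grubbs test: index of the most extreme value if
    significant at ``alpha``, else None.  Assumes approximate normality;
    zero-variance input returns None."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    return i if g > _grubbs_critical(n, alpha) else None


def grubbs_outliers(values, alpha: float = 0.05) -> list[int]:
    """Iterative Grubbs: repeatedly remove the single most extreme outlier
    until none is significant; returns original indices, detection order."""
    x = np.asarray(values, dtype=float)
    idx = np.arange(len(x))
    out: list[int] = []
    while len(x) >= 3:
        i = grubbs_test(x, alpha)
        if i is None:
            break
        out.append(int(idx[i]))
        x = np.delete(x, i)
        idx = np.delete(idx, i)
    return out
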