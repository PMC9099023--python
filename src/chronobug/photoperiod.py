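"""Diapause calling and photoperiodic-response-curve (CDL) fitting.

Reproductive diapause in the linden bug is scored from a two-week egg-laying
window plus ovary dissection of non-layers: a female is diapausing iff she
laid no eggs AND carries neither mature eggs nor vitellogenic oocytes.
Incidence as a function of day length L is modelled with a four-parameter
logistic

    p(L) = p_min + (p_max - p_min) / (1 + exp(slope * (L - L50)))

fitted by maximum binomial likelihood.  The critical day length (CDL) is
the day length at which the fitted incidence crosses 50% absolute (default)
or the midpoint of the asymptotes; its uncertainty comes from a seeded
nonparametric bootstrap over individual females.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DiapauseRecord",
    "PhotoperiodicCurve",
    "CDLFit",
    "call_diapause",
    "response_curve",
    "fit_cdl",
    "compare_cdl",
]


@dataclass(frozen=True)
class DiapauseRecord:
    """Reproductive status of one female at one photoperiod."""

    female_id: str
    genotype: str
    photoperiod_light_h: float
    laid_eggs: bool
    mature_eggs_present: bool | None = None
    vitellogenic_oocytes_present: bool | None = None


def call_diapause(record: DiapauseRecord) -> bool:
    """True iff the female is diapausing.

    Layers are reproductive regardless of ovary state.  Non-layers require
    dissection: lacking both mature eggs and vitellogenic oocytes means
    diapause; either present means a reproductive (pre-oviposition) female.
    Missing ovary fields for a non-layer are an error, since the protocol
    requires dissecting every non-layer.
    """
    if record.laid_eggs:
        return False
    if record.mature_eggs_present is None or record.vitellogenic_oocytes_present is None:
        raise ValueError(
            f"female {record.female_id}: non-layer without ovary dissection fields"
        )
    return not (record.mature_eggs_present or record.vitellogenic_oocytes_present)


@dataclass
class PhotoperiodicCurve:
    """Per-photoperiod binomial summary of diapause incidence."""

    photoperiods_h: np.ndarray
    n: np.ndarray
    k_diapause: np.ndarray
    genotype: str = ""

    def __post_init__(self) -> None:
        self.photoperiods_h = np.asarray(self.photoperiods_h, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.k_diapause = np.asarray(self.k_diapause, dtype=int)
        if np.any(self.k_diapause < 0) or np.any(self.k_diapause > self.n):
            raise ValueError("need 0 <= k <= n per photoperiod")

    @property
    def proportion(self) -> np.ndarray:
        return self.k_diapause / self.n

    @property
    def sem(self) -> np.ndarray:
        p = self.proportion
        return np.sqrt(p * (1.0 - p) / self.n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "photoperiod_h": self.photoperiods_h,
                "n": self.n,
                "k_diapause": self.k_diapause,
                "proportion": self.proportion,
                "sem": self.sem,
            }
        )


def response_curve(records: Sequence[DiapauseRecord]) -> PhotoperiodicCurve:
    """Tabulate diapause incidence per photoperiod from individual records."""
    if not records:
        raise ValueError("no records")
    by_L: dict[float, list[bool]] = {}
    for r in records:
        by_L.setdefault(r.photoperiod_light_h, []).append(call_diapause(r))
    Ls = sorted(by_L)
    genotypes = {r.genotype for r in records}
    return PhotoperiodicCurve(
        photoperiods_h=np.array(Ls),
        n=np.array([len(by_L[L]) for L in Ls]),
        k_diapause=np.array([sum(by_L[L]) for L in Ls]),
        genotype=genotypes.pop() if len(genotypes) == 1 else "mixed",
    )


@dataclass
class CDLFit:
    """Fitted logistic photoperiodic response with its CDL."""

    p_min: float
    p_max: float
    l50: float
    slope: float
    cdl_h: float
    cdl_sd_h: float | None
    cdl_ci: tuple[float, float] | None
    definition_mode: str
    extrapolated: bool
    degenerate: bool
    converged: bool
    log_likelihood: float
    bootstrap_cdls: np.ndarray | None = field(default=None, repr=False)

    def predict(self, L: np.ndarray | float) -> np.ndarray:
        return _logistic(np.asarray(L, dtype=float), self.p_min, self.p_max, self.l50, self.slope)


def _logistic(L, p_min, p_max, l50, slope):
    z = np.clip(slope * (np.asarray(L, dtype=float) - l50), -500.0, 500.0)
    return p_min + (p_max - p_min) / (1.0 + np.exp(z))


def _neg_loglik_grad(theta, L, k, n):
    """Binomial negative log-likelihood and its analytic gradient."""
    p_min, p_max, l50, slope = theta
    z = np.clip(slope * (L - l50), -500.0, 500.0)
    sig = 1.0 / (1.0 + np.exp(z))
    p = np.clip(p_min + (p_max - p_min) * sig, 1e-10, 1.0 - 1e-10)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))
    w = k / p - (n - k) / (1.0 - p)  # dLL/dp
    dsig = sig * (1.0 - sig)
    grad = -np.array(
        [
            np.sum(w * (1.0 - sig)),
            np.sum(w * sig),
            np.sum(w * (p_max - p_min) * dsig * slope),
            np.sum(w * (p_max - p_min) * dsig * -(L - l50)),
        ]
    )
    return nll, grad


def _cdl_from_params(p_min, p_max, l50, slope, mode):
    if mode == "midpoint":
        return l50
    # absolute 50% crossing of the fitted curve
    if not (p_min < 0.5 < p_max):
        return math.nan
    arg = (p_max - p_min) / (0.5 - p_min) - 1.0
    if arg <= 0:
        return math.nan
    return l50 + math.log(arg) / slope


def _fit_mle(L, k, n, pin_asymptotes):
    """Binomial ML fit: data-driven start (interpolated 50% crossing of the
    observed proportions), multistart fallback when it fails to converge."""
    if pin_asymptotes:
        bounds = [(0.0, 1e-9), (1.0 - 1e-9, 1.0), (L.min() - 6, L.max() + 6), (0.05, 60.0)]
    else:
        bounds = [(0.0, 0.5), (0.5, 1.0), (L.min() - 6, L.max() + 6), (0.05, 60.0)]
    prop = k / n
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # proportions decrease with L; first crossing of 0.5 as the L50 start
    below = np.nonzero(prop < 0.5)[0]
    l50_0 = float(L[below[0]]) if len(below) else float(L[-1])
    starts = [l50_0] + list(np.linspace(L.min(), L.max(), 3))
    best = None
    for j, s0 in enumerate(starts):
        x0 = np.clip(
            np.array([min(prop.min(), 0.49), max(prop.max(), 0.51), s0, 3.0]), lo, hi
        )
        res = minimize(
            _neg_loglik_grad, x0, args=(L, k, n),
            method="L-BFGS-B", jac=True, bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if j == 0 and res.success:
            break  # the data-driven start converged; skip the fallback grid
    return best


def fit_cdl(
    curve: PhotoperiodicCurve,
    mode: str = "absolute_50",
    bootstrap_b: int = 1000,
    seed: int = 0,
    pin_asymptotes: bool = False,
) -> CDLFit:
    """Fit the logistic response curve and locate the critical day length.

    ``mode`` "absolute_50" (default) reads the CDL where the fitted curve
    crosses incidence 0.5; "midpoint" reads the inflection L50 (the
    midpoint between the asymptotes).  ``cdl_sd_h`` and a percentile 95% CI
    come from ``bootstrap_b`` resamples of individuals within each
    photoperiod (set ``bootstrap_b=0`` to skip).  An all-diapause or
    all-reproductive curve is flagged degenerate with no CDL; a CDL outside
    the observed photoperiod range is flagged extrapolated.
    """
    if mode not in ("absolute_50", "midpoint"):
        raise ValueError("mode must be 'absolute_50' or 'midpoint'")
    L = curve.photoperiods_h
    k = curve.k_diapause.astype(float)
    n = curve.n.astype(float)
    if len(L) < 4:
        raise ValueError("need data at >= 4 photoperiods")
    if np.all(k == n) or np.all(k == 0):
        return CDLFit(
            math.nan, math.nan, math.nan, math.nan, math.nan, None, None,
            mode, False, degenerate=True, converged=False, log_likelihood=math.nan,
        )
    res = _fit_mle(L, k, n, pin_asymptotes)
    if not res.success and res.fun > 1e6:
        raise RuntimeError(f"CDL fit did not converge: {res.message}")
    p_min, p_max, l50, slope = res.x
    cdl = _cdl_from_params(p_min, p_max, l50, slope, mode)
    extrapolated = not (L.min() <= cdl <= L.max()) if math.isfinite(cdl) else True

    cdl_sd = ci = boots = None
    if bootstrap_b > 0:
        rng = np.random.default_rng(seed)
        vals = []
        n_int = curve.n
        for _ in range(bootstrap_b):
            k_b = rng.binomial(n_int, k / n)  # resample individuals within condition
            if np.all(k_b == n_int) or np.all(k_b == 0):
                continue
            r = _fit_mle(L, k_b.astype(float), n, pin_asymptotes)
            c = _cdl_from_params(*r.x, mode)
            if math.isfinite(c):
                vals.append(c)
        if len(vals) >= max(10, bootstrap_b // 2):
            boots = np.array(vals)
            cdl_sd = float(np.std(boots, ddof=1))
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return CDLFit(
        float(p_min), float(p_max), float(l50), float(slope), float(cdl),
        cdl_sd, ci, mode, bool(extrapolated), degenerate=False,
        converged=bool(res.success), log_likelihood=float(-res.fun),
        bootstrap_cdls=boots,
    )


def compare_cdl(fit_a: CDLFit, fit_b: CDLFit) -> dict:
    """Difference of two CDLs with combined SD and, when both fits carry
    bootstrap replicates, a percentile CI of the difference."""
    if fit_a.definition_mode != fit_b.definition_mode:
        raise ValueError("CDL fits use different definition modes")
    if fit_a.degenerate or fit_b.degenerate:
        raise ValueError("cannot compare a degenerate fit")
    delta = fit_a.cdl_h - fit_b.cdl_h
    sd = None
    if fit_a.cdl_sd_h is not None and fit_b.cdl_sd_h is not None:
        sd = math.hypot(fit_a.cdl_sd_h, fit_b.cdl_sd_h)
    ci = None
    if fit_a.bootstrap_cdls is not None and fit_b.bootstrap_cdls is not None:
        m = min(len(fit_a.bootstrap_cdls), len(fit_b.bootstrap_cdls))
        diffs = fit_a.bootstrap_cdls[:m] - fit_b.bootstrap_cdls[:m]
        ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    return {"delta_h": float(delta), "sd_h": sd, "ci_95": ci}
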