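"""Free-running rhythm analysis in constant conditions.

The classical normalised Lomb-Scargle periodogram is computed with
Scargle's time-offset formulation on mean-subtracted counts: at each test
frequency the power is the explained sum of squares of the least-squares
sine+cosine fit divided by twice the sample variance, so under Gaussian
noise each power is approximately Exp(1) distributed.  Missing bins are
simply omitted (the estimator handles gaps natively).

Significance uses the independent-frequency approximation
``P(max power > z) = 1 - (1 - e^(-z))^M`` with ``M`` = number of grid
frequencies divided by the oversampling factor; a seeded permutation mode
is available as an exact alternative.  An animal is scored *rhythmic*
(one significant peak; its period, refined by parabolic interpolation in
frequency, is the free-running period tau), *complex* (two or more
well-separated significant peaks) or *arrhythmic* (none).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schedules import ActivitySeries

__all__ = [
    "Periodogram",
    "FreeRunResult",
    "lomb_scargle",
    "significance_threshold",
    "classify_freerun",
]

DEFAULT_PERIOD_RANGE = (16.0, 35.0)  # hours; covers insect tau extremes with margin


@dataclass
class Periodogram:
    """Normalised Lomb-Scargle power on a descending period grid."""

    periods_h: np.ndarray
    power: np.ndarray
    n_effective: int
    oversampling: int
    span_h: float

    def peak_period(self) -> float:
        """Highest-power period, refined by parabolic interpolation of the
        power maximum in frequency."""
        i = int(np.argmax(self.power))
        f = 1.0 / self.periods_h
        if 0 < i < len(f) - 1:
            y0, y1, y2 = self.power[i - 1], self.power[i], self.power[i + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                shift = 0.5 * (y0 - y2) / denom
                df = f[i + 1] - f[i]
                return float(1.0 / (f[i] + shift * df))
        return float(self.periods_h[i])


def _check_constant_conditions(series: ActivitySeries) -> None:
    t = series.times_h()
    t0, t1 = t[0], t[-1] + series.bin_minutes / 60.0
    for tt, _state in series.schedule.transitions():
        if t0 < tt < t1:
            raise ValueError(
                "constant conditions required: light transition at "
                f"{tt:.2f} h inside the analysed span"
            )


def lomb_scargle(
    series: ActivitySeries,
    period_min_h: float = DEFAULT_PERIOD_RANGE[0],
    period_max_h: float = DEFAULT_PERIOD_RANGE[1],
    oversampling: int = 4,
    min_days: float = 5.0,
    require_constant: bool = True,
) -> Periodogram:
    """Classical normalised Lomb-Scargle periodogram of an activity series.

    The frequency grid spans ``[1/period_max, 1/period_min]`` at
    ``oversampling`` times the natural resolution ``1/span``.  A constant
    series yields all-zero power.
    """
    if period_min_h >= period_max_h:
        raise ValueError("period_min must be < period_max")
    if series.n_days < min_days:
        raise ValueError(f"need >= {min_days} days of data")
    if require_constant:
        _check_constant_conditions(series)
    t = series.times_h()
    y = series.counts.astype(float)
    ok = ~series.missing & np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(y)
    span = series.n_days * 24.0
    df = 1.0 / (span * oversampling)
    freqs = np.arange(1.0 / period_max_h, 1.0 / period_min_h + df / 2, df)
    periods = 1.0 / freqs[::-1]  # descending periods

    power = _ls_power(t, y, freqs)
    return Periodogram(periods, power[::-1], n, oversampling, span)


def _ls_power(t: np.ndarray, y: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Scargle-normalised power at each frequency (ascending ``freqs``)."""
    y = y - y.mean()
    var = y.var(ddof=1)
    if var == 0:
        return np.zeros_like(freqs)
    power = np.empty_like(freqs)
    for i, f in enumerate(freqs):
        w = 2.0 * math.pi * f
        # Scargle's tau makes the cos/sin regressors orthogonal, so the
        # explained SS decouples into the two projection terms
        s2 = np.sum(np.sin(2.0 * w * t))
        c2 = np.sum(np.cos(2.0 * w * t))
        tau = math.atan2(s2, c2) / (2.0 * w)
        ct = np.cos(w * (t - tau))
        st = np.sin(w * (t - tau))
        power[i] = 0.5 * (
            np.dot(y, ct) ** 2 / np.dot(ct, ct) + np.dot(y, st) ** 2 / np.dot(st, st)
        )
    return power / var


def significance_threshold(
    periodogram: Periodogram,
    alpha: float = 0.05,
    method: str = "analytic",
    series: ActivitySeries | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    m_effective: float | None = None,
    **ls_kwargs,
) -> float:
    """Power level exceeded by the periodogram maximum with probability
    ``alpha`` under the no-rhythm null.

    Analytic mode uses the exponential-tail closed form
    ``z = -ln(1 - (1-alpha)^(1/M))``.  The default trial count ``M`` is the
    full number of grid frequencies (a Bonferroni-flavoured choice: the
    maximum of an oversampled power curve exceeds the natural-resolution
    maximum, so counting only ``n_grid/oversampling`` "independent"
    frequencies is anti-conservative); ``m_effective`` overrides it.
    Permutation mode shuffles the counts of ``series`` (seeded) and takes
    the empirical (1-alpha) quantile of the maximum power.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if method == "analytic":
        m = float(m_effective) if m_effective else float(len(periodogram.periods_h))
        m = max(1.0, m)
        if alpha == 1.0:
            return 0.0
        return float(-math.log(1.0 - (1.0 - alpha) ** (1.0 / m)))
    if method == "permutation":
        if series is None:
            raise ValueError("permutation mode needs the activity series")
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_permutations)
        base = series.counts.copy()
        for b in range(n_permutations):
            shuffled = ActivitySeries(
                series.animal_id,
                rng.permutation(base),
                series.bin_minutes,
                series.schedule,
                start_h=series.start_h,
            )
            pg = lomb_scargle(
                shuffled,
                periodogram.periods_h.min(),
                periodogram.periods_h.max(),
                periodogram.oversampling,
                require_constant=False,
                **ls_kwargs,
            )
            maxima[b] = pg.power.max()
        return float(np.quantile(maxima, 1.0 - alpha))
    raise ValueError("method must be 'analytic' or 'permutation'")


@dataclass
class FreeRunResult:
    """Rhythmicity call in constant conditions.

    ``tau_h`` is present iff the call is ``"rhythmic"``; ``peak_powers``
    lists (period_h, power) of every significant merged peak.
    """

    call: str
    tau_h: float | None
    peak_powers: list[tuple[float, float]]
    threshold: float
    animal_id: str = ""


def classify_freerun(
    series: ActivitySeries,
    period_min_h: float = DEFAULT_PERIOD_RANGE[0],
    period_max_h: float = DEFAULT_PERIOD_RANGE[1],
    oversampling: int = 4,
    alpha: float = 0.05,
    merge_window_h: float = 0.5,
    max_components: int = 3,
) -> FreeRunResult:
    """Score an animal rhythmic / complex / arrhythmic in constant
    conditions and estimate tau for rhythmic animals.

    Periodic components are extracted by iterative prewhitening: the
    strongest significant periodogram peak is located (parabolic
    interpolation in frequency), the least-squares sinusoid at that
    frequency is subtracted, and the residual is re-tested, up to
    ``max_components`` times.  Prewhitening keeps spectral-leakage
    sidelobes of a strong rhythm from masquerading as extra components; a
    new peak within ``merge_window_h`` of one already found is treated as
    a residual artifact of the same component and stops the search.  One
    component means rhythmic (tau = its period), two or more complex,
    none arrhythmic.
    """
    pg = lomb_scargle(series, period_min_h, period_max_h, oversampling)
    thr = significance_threshold(pg, alpha)

    t = series.times_h()
    y = series.counts.astype(float)
    ok = ~series.missing & np.isfinite(y)
    t, y = t[ok], y[ok]
    span = series.n_days * 24.0
    df = 1.0 / (span * oversampling)
    freqs = np.arange(1.0 / period_max_h, 1.0 / period_min_h + df / 2, df)
    periods_desc = 1.0 / freqs[::-1]

    resid = y.copy()
    components: list[tuple[float, float]] = []  # (period_h, power)
    for _ in range(max_components):
        power = _ls_power(t, resid, freqs)[::-1]  # align with periods_desc
        sub = Periodogram(periods_desc, power, len(resid), oversampling, span)
        if power.max() <= thr:
            break
        per = sub.peak_period()
        if any(abs(per - c[0]) <= merge_window_h for c in components):
            break
        components.append((float(per), float(power.max())))
        # project out the whole periodic waveform at the refined frequency:
        # a rhythmic component is periodic, not sinusoidal, and its
        # harmonics (even outside the search range) leak into it
        w = 2.0 * np.pi / per
        cols = [np.ones_like(t)]
        for k in (1, 2, 3):
            cols += [np.cos(k * w * t), np.sin(k * w * t)]
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
        resid = resid - X @ beta

    if len(components) == 0:
        return FreeRunResult("arrhythmic", None, [], thr, series.animal_id)
    if len(components) == 1:
        return FreeRunResult(
            "rhythmic", components[0][0], components, thr, series.animal_id
        )
    return FreeRunResult("complex", None, components, thr, series.animal_id)
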