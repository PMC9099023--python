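"""Synthetic cohorts with the statistical structure the analyses assume.

Activity agents are inhomogeneous Poisson counters.  The per-bin expected
count is

    lambda(t) = max(0, b * (1 + m(t)) + A * bump(theta(t)) + L * I_light(t))

where ``b`` is the baseline rate (counts per 5-min bin), ``bump`` is a von
Mises-shaped circadian drive peaking at ``clock_peak_zt`` (normalised to
peak 1), ``L`` is an additive drive while lights are on, and ``m`` is a
masking state that jumps by ``+g_D`` at every lights-off and ``-g_L`` at
every lights-on and relaxes back to 0 exponentially with time constant
``mask_decay_hours``.  The clock phase ``theta`` advances at a 24-h period
while the light program cycles and at ``tau_free`` once the program becomes
constant, continuing from its phase at release.  Masking enters
multiplicatively on the baseline so that suppression can never drive the
expected rate negative (the rate clamps at 0).

With a masking jump ``g`` the transient after a light switch decays as
``g * exp(-t / mask_decay_hours)``: within three time constants the
residual is under 5% of the jump, which for decay constants of 1.5-2 h
spans roughly 4.5-6 h, the transient length this generator is built to
emulate.

Beyond activity, the module generates binomial diapause cohorts on a
logistic photoperiodic response, qPCR Cq tables with dilution-series
standard curves, and grayscale blob images for densitometry.
Everything is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .photoperiod import DiapauseRecord
from .schedules import ActivitySeries, LightSchedule

__all__ = [
    "AgentParams",
    "GenotypePreset",
    "PhotoperiodicModel",
    "PRESETS",
    "expected_rate",
    "simulate_agent",
    "simulate_cohort",
    "simulate_photoperiodic_cohort",
    "simulate_qpcr",
    "simulate_brain_image",
]


@dataclass(frozen=True)
class AgentParams:
    """Rate-model parameters of one activity agent.

    All rates are expected counts per 5-min bin; time constants in hours.
    """

    baseline_rate: float = 2.0
    clock_amplitude_ld: float = 0.0
    clock_amplitude_const: float = 0.0
    clock_peak_zt: float = 9.0
    clock_width: float = 3.0  # von Mises concentration kappa
    tau_free: float = 24.2
    light_drive: float = 0.0
    mask_gain_dark: float = 0.0
    mask_gain_light: float = 0.0
    mask_decay_hours: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.mask_gain_dark < 0 or self.mask_gain_light < 0:
            raise ValueError("masking gains must be >= 0")
        if self.mask_decay_hours <= 0:
            raise ValueError("mask_decay_hours must be > 0")
        if not (16.0 < self.tau_free < 32.0):
            raise ValueError("tau_free must lie in (16, 32) h")


@dataclass(frozen=True)
class GenotypePreset:
    """An agent-parameter template plus the fraction of agents that carry
    the periodic / masking drive; the remainder are pure-noise agents."""

    name: str
    params: AgentParams
    ld_rhythmic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ld_rhythmic_fraction <= 1.0):
            raise ValueError("ld_rhythmic_fraction must lie in [0, 1]")


# Documented simulator defaults: these reproduce the qualitative contrasts
# the analyses must detect (diurnal clock-driven wild type; nocturnal
# masking-driven, DD-arrhythmic pdf-null; light-driven cry-m diurnal in LD
# only; pdf-RK = wild type with a ~45-min longer free-running period).
# They are simulator choices, not measurements.
PRESETS: dict[str, GenotypePreset] = {
    "WT": GenotypePreset(
        "WT",
        AgentParams(
            baseline_rate=2.0,
            clock_amplitude_ld=6.0,
            clock_amplitude_const=6.0,
            clock_peak_zt=9.0,
            tau_free=24.2,
            mask_gain_dark=0.5,
            mask_gain_light=0.5,
        ),
        ld_rhythmic_fraction=1.0,
    ),
    "pdf-null": GenotypePreset(
        "pdf-null",
        AgentParams(
            baseline_rate=2.0,
            clock_amplitude_ld=0.0,
            clock_amplitude_const=0.0,
            mask_gain_dark=4.0,
            mask_gain_light=4.0,
            mask_decay_hours=2.0,
        ),
        ld_rhythmic_fraction=0.75,
    ),
    "cry-m": GenotypePreset(
        "cry-m",
        AgentParams(
            baseline_rate=2.0,
            clock_amplitude_ld=0.0,
            clock_amplitude_const=0.0,
            light_drive=6.0,
            mask_gain_dark=0.5,
            mask_gain_light=0.5,
        ),
        ld_rhythmic_fraction=1.0,
    ),
    "pdf-RK": GenotypePreset(
        "pdf-RK",
        AgentParams(
            baseline_rate=2.0,
            clock_amplitude_ld=6.0,
            clock_amplitude_const=6.0,
            clock_peak_zt=9.0,
            tau_free=24.95,
            mask_gain_dark=0.5,
            mask_gain_light=0.5,
        ),
        ld_rhythmic_fraction=1.0,
    ),
}


def _null_params(params: AgentParams) -> AgentParams:
    """Strip every systematic drive, leaving a constant-rate Poisson agent."""
    return replace(
        params,
        clock_amplitude_ld=0.0,
        clock_amplitude_const=0.0,
        light_drive=0.0,
        mask_gain_dark=0.0,
        mask_gain_light=0.0,
    )


def _release_hour(schedule: LightSchedule) -> float | None:
    """Start (h from origin) of the trailing constant-light-state stretch,
    or None if the program cycles to the end.  A trailing run shorter than
    24 h is part of the cycle, not a constant condition."""
    segs = schedule.segments
    i = len(segs) - 1
    state = segs[i].light_on
    while i > 0 and segs[i - 1].light_on == state:
        i -= 1
    start = segs[i].start_h
    if schedule.span_h - start >= 24.0 - 1e-9:
        return float(start)
    return None


def _clock_phase(t_h: np.ndarray, schedule: LightSchedule, tau_free: float) -> np.ndarray:
    """Clock phase in radians: 24-h entrained before release into constant
    conditions, free-running at tau_free after."""
    release = _release_hour(schedule)
    theta = 2.0 * np.pi * np.mod(t_h, 24.0) / 24.0
    if release is not None:
        theta_rel = 2.0 * np.pi * (release % 24.0) / 24.0
        free = theta_rel + 2.0 * np.pi * (t_h - release) / tau_free
        theta = np.where(t_h >= release, np.mod(free, 2.0 * np.pi), theta)
    return theta


def _mask_state(t_h: np.ndarray, schedule: LightSchedule, params: AgentParams) -> np.ndarray:
    """Masking state m(t): exponential relaxation with jumps at switches."""
    m = np.zeros_like(t_h, dtype=float)
    if params.mask_gain_dark == 0.0 and params.mask_gain_light == 0.0:
        return m
    tau_m = params.mask_decay_hours
    for t_k, new_state in schedule.transitions():
        jump = -params.mask_gain_light if new_state else params.mask_gain_dark
        after = t_h >= t_k
        m[after] += jump * np.exp(-(t_h[after] - t_k) / tau_m)
    return m


def expected_rate(
    params: AgentParams, schedule: LightSchedule, t_h: np.ndarray
) -> np.ndarray:
    """Deterministic expected counts per 5-min bin at times ``t_h`` (hours
    from the schedule origin)."""
    t_h = np.asarray(t_h, dtype=float)
    b = params.baseline_rate
    m = _mask_state(t_h, schedule, params)
    lam = b * (1.0 + m)

    release = _release_hour(schedule)
    amp = np.full_like(t_h, params.clock_amplitude_ld)
    if release is not None:
        amp[t_h >= release] = params.clock_amplitude_const
    if np.any(amp > 0):
        theta = _clock_phase(t_h, schedule, params.tau_free)
        peak = 2.0 * np.pi * params.clock_peak_zt / 24.0
        bump = np.exp(params.clock_width * (np.cos(theta - peak) - 1.0))
        lam = lam + amp * bump
    if params.light_drive != 0.0:
        lam = lam + params.light_drive * schedule.light_states(t_h).astype(float)
    return np.maximum(lam, 0.0)


def simulate_agent(
    params: AgentParams,
    schedule: LightSchedule,
    seed: int | np.random.SeedSequence = 0,
    bin_minutes: int = 5,
    animal_id: str = "agent",
    genotype: str = "",
) -> ActivitySeries:
    """Draw one agent's Poisson count series over the whole schedule span."""
    if schedule.span_h < 24.0 - 1e-9:
        raise ValueError("schedule span must cover at least one day")
    n_bins = int(round(schedule.span_h * 60.0 / bin_minutes))
    t_h = np.arange(n_bins) * bin_minutes / 60.0
    lam = expected_rate(params, schedule, t_h) * (bin_minutes / 5.0)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(float)
    return ActivitySeries(
        animal_id, counts, bin_minutes, schedule, start_h=0.0, genotype=genotype
    )


def simulate_cohort(
    preset: GenotypePreset | str,
    n: int,
    schedule: LightSchedule,
    seed: int = 0,
    bin_minutes: int = 5,
) -> list[ActivitySeries]:
    """Simulate ``n`` agents of a genotype preset.

    Per-animal seeds are spawned from the cohort seed with
    ``numpy.random.SeedSequence`` so results do not depend on iteration
    order.  The first ``round(n * ld_rhythmic_fraction)`` agents carry the
    preset drive; the rest are constant-rate noise agents.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise KeyError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
    if n < 1:
        raise ValueError("n must be >= 1")
    n_driven = int(round(n * preset.ld_rhythmic_fraction))
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i in range(n):
        p = preset.params if i < n_driven else _null_params(preset.params)
        out.append(
            simulate_agent(
                p,
                schedule,
                seed=children[i],
                bin_minutes=bin_minutes,
                animal_id=f"{preset.name}-{i + 1:03d}",
                genotype=preset.name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# photoperiodic response


@dataclass(frozen=True)
class PhotoperiodicModel:
    """Logistic diapause-incidence model: the probability of diapause
    decreases with day length L as

        p(L) = p_min + (p_max - p_min) / (1 + exp(slope * (L - cdl_true)))

    so ``cdl_true`` is the midpoint of the transition and ``slope`` its
    steepness (per hour).
    """

    cdl_true: float = 16.4
    slope: float = 3.0
    p_min: float = 0.0
    p_max: float = 1.0
    n_per_condition: int = 30
    photoperiods: tuple[float, ...] = tuple(np.linspace(8.0, 18.0, 11))

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ValueError("need 0 <= p_min <= p_max <= 1")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not self.photoperiods:
            raise ValueError("photoperiods must be non-empty")

    def p_diapause(self, photoperiod_h: float | np.ndarray) -> np.ndarray:
        L = np.asarray(photoperiod_h, dtype=float)
        return self.p_min + (self.p_max - self.p_min) / (
            1.0 + np.exp(self.slope * (L - self.cdl_true))
        )


def simulate_photoperiodic_cohort(
    model: PhotoperiodicModel, seed: int = 0, genotype: str = "sim"
) -> list[DiapauseRecord]:
    """Bernoulli diapause calls per female, with egg/ovary fields made
    consistent with the call (diapausing females laid nothing and carry no
    developing oocytes; reproductive females mostly laid eggs, a few are
    pre-oviposition with vitellogenic oocytes)."""
    rng = np.random.default_rng(seed)
    records = []
    for L in model.photoperiods:
        p = float(model.p_diapause(L))
        for i in range(model.n_per_condition):
            diapausing = bool(rng.random() < p)
            if diapausing:
                laid, mature, vitell = False, False, False
            else:
                laid = bool(rng.random() < 0.8)
                # non-layers among reproductive females still show ovary development
                mature = not laid and bool(rng.random() < 0.5)
                vitell = not laid and not mature
            records.append(
                DiapauseRecord(
                    female_id=f"{genotype}-L{L:g}-{i + 1:03d}",
                    genotype=genotype,
                    photoperiod_light_h=float(L),
                    laid_eggs=laid,
                    mature_eggs_present=mature,
                    vitellogenic_oocytes_present=vitell,
                )
            )
    return records


# ---------------------------------------------------------------------------
# qPCR fixtures


def simulate_qpcr(
    true_ratios: dict[str, float],
    efficiencies: dict[str, float],
    noise_sd_cq: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    target_gene: str = "pdf",
    reference_gene: str = "rp49",
    calibrator_cq: float = 22.0,
    reference_cq: float = 18.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format Cq table plus five-point dilution series.

    ``true_ratios`` maps sample_id -> relative target expression versus the
    calibrator sample (ratio 1).  Cq for the target in sample s is
    ``calibrator_cq - log_E(ratio_s) + noise``; the reference gene sits at
    ``reference_cq`` in every sample.  The dilution series for each gene
    follows the exact line with slope ``-1/log10(E)``.
    """
    if noise_sd_cq < 0:
        raise ValueError("noise_sd_cq must be >= 0")
    for g, E in efficiencies.items():
        if not (1.0 < E <= 2.0):
            raise ValueError(f"efficiency of {g} must lie in (1, 2]")
    for s, r in true_ratios.items():
        if r <= 0:
            raise ValueError(f"ratio of sample {s} must be > 0")
    rng = np.random.default_rng(seed)
    E_t = efficiencies[target_gene]
    E_r = efficiencies[reference_gene]
    rows = []
    for sample, ratio in true_ratios.items():
        cq_t = calibrator_cq - math.log(ratio, E_t)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sample,
                    "gene": target_gene,
                    "replicate": rep,
                    "cq": cq_t + rng.normal(0.0, noise_sd_cq),
                }
            )
            rows.append(
                {
                    "sample_id": sample,
                    "gene": reference_gene,
                    "replicate": rep,
                    "cq": reference_cq + rng.normal(0.0, noise_sd_cq),
                }
            )
    cq_table = pd.DataFrame(rows)

    dil_rows = []
    for gene, E in ((target_gene, E_t), (reference_gene, E_r)):
        base = calibrator_cq if gene == target_gene else reference_cq
        for log10_dil in (0.0, -1.0, -2.0, -3.0, -4.0):
            dil_rows.append(
                {
                    "gene": gene,
                    "log10_dilution": log10_dil,
                    "cq": base - log10_dil / math.log10(E),
                }
            )
    dilution_table = pd.DataFrame(dil_rows)
    return cq_table, dilution_table


# ---------------------------------------------------------------------------
# densitometry fixtures


@dataclass
class SyntheticImage:
    """A synthetic grayscale plane plus ground truth for densitometry tests."""

    pixels: np.ndarray
    scale_um_per_px: float
    background_level: float
    blob_masks: list[np.ndarray] = field(default_factory=list)


def simulate_brain_image(
    cell_centers_um: Sequence[tuple[float, float]],
    cell_intensities: Sequence[float],
    background_level: float = 100.0,
    noise_sd: float = 0.0,
    scale_um_per_px: float = 1.0,
    shape_px: tuple[int, int] = (256, 256),
    blob_sigma_um: float = 8.0,
    seed: int = 0,
) -> SyntheticImage:
    """Gaussian-profile blobs on a uniform background with pixel noise.

    Each blob adds ``I * exp(-r^2 / (2 sigma^2))`` (peak amplitude ``I``);
    the mean added intensity over a window of area A containing the whole
    blob is analytically ``I * 2 pi sigma_px^2 / A``.  Ground-truth masks
    (r <= 2 sigma) are returned alongside.
    """
    if scale_um_per_px <= 0:
        raise ValueError("scale must be positive")
    if any(i < 0 for i in cell_intensities):
        raise ValueError("cell intensities must be >= 0")
    if len(cell_centers_um) != len(cell_intensities):
        raise ValueError("centers and intensities length mismatch")
    rng = np.random.default_rng(seed)
    h, w = shape_px
    img = np.full((h, w), float(background_level))
    yy, xx = np.mgrid[0:h, 0:w]
    sigma_px = blob_sigma_um / scale_um_per_px
    masks = []
    for (cx_um, cy_um), amp in zip(cell_centers_um, cell_intensities):
        cx, cy = cx_um / scale_um_per_px, cy_um / scale_um_per_px
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        img += amp * np.exp(-r2 / (2.0 * sigma_px**2))
        masks.append(r2 <= (2.0 * sigma_px) ** 2)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return SyntheticImage(
        pixels=img,
        scale_um_per_px=scale_um_per_px,
        background_level=float(background_level),
        blob_masks=masks,
    )
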