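# chronobug

Circadian and photoperiodic analysis of insect locomotor-activity
experiments, built around the linden bug *Pyrrhocoris apterus* — a species
with a weakly expressed circadian rhythm but an unusually robust
photoperiodic (seasonal) response.  The package re-implements, as tested
library code, the quantitative chain such experiments need:

- **Activity-monitor I/O and light programs** — tab-separated
  Trikinetics-style monitor files (5-min count bins), light/dark schedules
  with pulses and constant segments, Zeitgeber-time (ZT) bookkeeping with
  ZT0 = lights-on.
- **Light–dark-cycle analysis** — smoothed average-day profiles
  (circular Gaussian, σ = 20 min), rhythmic/arrhythmic-in-LD scoring by
  peak counting, activity onset/offset as median-threshold crossings,
  light-vs-dark activity partition, and responses to 2-h light/dark pulses.
- **Free-running analysis** — classical normalised Lomb–Scargle
  periodogram with exponential-tail significance, iterative prewhitening,
  and the rhythmic / complex / arrhythmic call with free-running period τ.
- **Rhythm statistics** — a JTK_CYCLE-style rank test (Kendall's S against
  phased cosine reference orderings with an exact Harding/Jonckheere–
  Terpstra null), Rayleigh test, two-sample Watson U² with permutation
  p-values, Grubbs outlier test.
- **qPCR relative expression** — five-point standard-curve efficiencies
  (E = 10^(−1/slope)) and the efficiency-corrected (Pfaffl-form) ratio
  against an *rp49* reference and calibrator sample.
- **Densitometry** — ROI mean gray values with nearby-background
  subtraction and hemisphere averaging for stained somata and projection
  fields.
- **Photoperiodism** — diapause calling from egg-laying and ovary state,
  binomial photoperiodic response curves, and maximum-likelihood logistic
  fits of the critical day length (CDL) with bootstrap uncertainty.
- **Synthetic cohorts** — Poisson activity agents with a von Mises-shaped
  clock drive and a clock-independent *masking* response to light switches
  (exponentially decaying transients), plus binomial diapause cohorts,
  qPCR tables and blob-image fixtures.  The generator provides ground
  truth for every analysis above; presets mimic wild-type (diurnal,
  rhythmic), *pdf*-null-like (nocturnal by masking, arrhythmic in
  constant darkness), *cry-m*-like (light-driven diurnal only) and
  long-τ phenotypes.

## The core quantities

Activity of animal *i* in 5-min bins is modelled as
λ(t) = max(0, b·(1+m(t)) + A·exp(κ(cos(θ(t)−θ_peak)−1)) + L·I_light(t)),
where the masking state m jumps at light switches and decays with time
constant τ_m.  Rhythmicity in constant conditions is tested with the
normalised Lomb–Scargle power P(ω) (equal, at every frequency, to the
variance explained by the least-squares sinusoid at ω over twice the
sample variance), with the max-power null P(max > z) = 1 − (1 − e^(−z))^M.
The photoperiodic response is p(L) = p_min + (p_max − p_min)/(1 +
exp(s(L − L50))), fitted by binomial maximum likelihood; the CDL is the
day length where fitted diapause incidence crosses 50%.

## Worked example

```python
from chronobug.pipeline import RunConfig, CohortSpec, run_experiment

cfg = RunConfig(
    label="LD18:6", entrainment_days=5,
    constant_days=10, constant_condition="DD",
    cohorts=[CohortSpec("WT", 16, 1), CohortSpec("pdf-null", 16, 2)],
)
run_experiment(cfg, "demo/")
```

simulates 16 wild-type-like and 16 *pdf*-null-like bugs through 5 days of
LD 18:6 entrainment plus 10 days of constant darkness, scores every
animal, and writes `demo/animals.tsv` and `demo/summary.json`:

```json
{
  "WT":       {"n": 16, "pct_rhythmic_ld": 100.0, "pct_rhythmic_const": 93.75,
               "tau_mean_h": 24.18, "onset_circ_mean_zt": 3.82, ...},
  "pdf-null": {"n": 16, "pct_rhythmic_ld": 75.0,  "pct_arrhythmic_const": 93.75,
               "onset_circ_mean_zt": 16.18, ...}
}
```

Read: every wild-type agent is rhythmic under the LD cycle with activity
onset near ZT3.8 (mid-morning) and 93.75% keep a free-running rhythm in
darkness with mean τ ≈ 24.2 h, while the masking-driven cohort turns
nocturnal (onset at ZT16.2, right before lights-off at ZT18), 25% are
arrhythmic in LD, and 93.75% lose rhythmicity immediately in constant
darkness — the diagnostic contrast between clock-driven and light-driven
behaviour.

The same verbs are available from a shell:
`chronobug simulate|diel|freerun|stats|qpcr|densito|ppr|run`
(see `chronobug --help`; image reading for `densito` needs the optional
`pillow` extra).

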