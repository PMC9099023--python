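# Methods

This note records the models, estimators, numerical conventions and
design choices behind `chronobug`, and what the synthetic-data validation
does and does not establish about real recordings.

## Time and light conventions

All intervals are half-open `[start, end)`; a 5-min bin belongs to the
light state at its start, which removes double counting at switches.
Zeitgeber time is hours since lights-on (ZT0 = lights-on); after release
into constant darkness or light, ZT continues on the 24-h phase of the
preceding cycle, so "ZT8 on the first DD day" is well defined.  Monitor
rows whose status flag marks a reader error are kept as missing bins and
excluded from statistics; analyses requiring near-contiguous data should
drop animals with more than ~5% missing bins.

## The activity-agent model

Each synthetic animal is an inhomogeneous Poisson counter with per-bin
mean

    lambda(t) = max(0, b (1 + m(t)) + A exp(kappa (cos(theta(t) - theta_p) - 1)) + L I_light(t))

* `b` — baseline rate (counts per 5-min bin; default 2).
* Clock drive — a von Mises-shaped bump (peak 1, concentration `kappa`,
  default 3) rather than a sinusoid, so diurnal activity is confined to a
  mid-day window; amplitude `A` may differ between entrained and constant
  conditions.  The phase `theta` runs at 24 h while the light program
  cycles and at the free-running period `tau_free` afterwards, continuing
  from the release phase.  A trailing constant-state stretch counts as
  "constant conditions" only if it lasts at least 24 h.
* Masking — a clock-independent state `m` that jumps by `+g_D` at every
  lights-off and `-g_L` at every lights-on and relaxes to zero
  exponentially with time constant `tau_m` (default 2 h).  Masking enters
  multiplicatively on the baseline and the rate clamps at zero, so
  suppression can never produce negative rates.  The transient therefore
  decays to under 5% of its initial amplitude within `3 tau_m` — about
  4.5–6 h for `tau_m` of 1.5–2 h, the transient length the generator is
  designed to emulate.  Note the 5% is measured against the transient
  amplitude, not against the baseline: with a strong jump (`g = 4`) the
  *absolute* rate is still ~20% above baseline at `3 tau_m`.
* `L` — an additive drive while lights are on, used by the light-driven
  (cry-m-like) preset that is diurnal under LD but arrhythmic in DD.

Presets (`WT`, `pdf-null`, `cry-m`, `pdf-RK`) encode the qualitative
phenotype contrasts the analyses must detect; their numeric values are
simulator choices, not measurements.  The pdf-null preset mixes 75%
masking-responder agents with 25% constant-rate agents.  Per-animal seeds
are spawned from the cohort seed with `numpy.random.SeedSequence`, so
outputs are reproducible and independent of iteration order.

What the generator does *not* emulate: inter-animal coupling, temperature
effects, slow trends in activity level (ageing, feeding), non-Poisson
burstiness of real locomotion, and phase lability of real clocks.
Passing closed-loop tests therefore demonstrates the *estimators* are
correct and calibrated under the stated stochastic model, not that real
bugs satisfy that model.

## Average-day profiles, LD scoring, onset/offset

Profiles live on the modulo-24-h ZT grid.  Smoothing is circular
convolution with a wrapped Gaussian kernel normalised to sum 1 (sigma in
minutes, default 20), which conserves the profile sum exactly and has no
edge bias at ZT0.

An animal is **rhythmic in LD** when its smoothed multi-day average-day
trace shows exactly one circular local maximum with prominence at least
25% of the trace range and separation at least 4 h (both configurable).
A stricter per-day mode applies the same count to every single day;
single-day Poisson noise makes it fail cleanly unimodal animals at a
non-trivial rate, so the averaged trace — the one the standard actogram
"average activity" workflow inspects — is the default.  All-zero days
flag the animal inactive.

**Onset/offset** use the median of the smoothed 24-h profile as the
threshold.  Both crossings bound the above-threshold segment containing
the profile maximum: the onset is the upward crossing found scanning
backward (circularly) from the maximum, the offset the downward crossing
scanning forward from it, each linearly interpolated between bins.
Anchoring both scans at the peak is essential on profiles with long
inactive stretches, where the median threshold runs through baseline
noise and a min-anchored scan would latch onto noise ripples; on
noiseless unimodal profiles the peak-anchored and min-anchored rules
coincide.  Under the bin-start value convention, a square profile with a
step at ZT4 yields an onset one bin before the step edge (ZT 3.9167 at
5-min bins) and an offset exactly at the down-step; a triangular profile
yields exact symmetric crossings.  Onset/offset are equivariant to
circular shifts to numerical precision.  Per-animal onset jitter under
the WT preset is ~26 min SD, so cohort phase contrasts at ±10 min
resolution need on the order of 100 animals per group.

## Free-running analysis

The Lomb–Scargle periodogram uses Scargle's time-offset formulation on
mean-subtracted counts; the reported power at each frequency equals the
explained sum of squares of the least-squares sine+cosine fit divided by
twice the sample variance (ddof 1), so each power is ~Exp(1) under
Gaussian noise.  Missing bins are omitted (the estimator handles gaps
natively).  The default search range is 16–35 h with 4× frequency
oversampling; the peak period is refined by parabolic interpolation in
frequency, giving τ errors well below the grid step (~0.02 h mean
absolute error at 12 days of 5-min data).

Significance uses the closed form `z = -ln(1 - (1 - alpha)^(1/M))`.  `M`
defaults to the *full* grid-frequency count: the continuum maximum of an
oversampled power curve exceeds the natural-resolution maximum, and
counting only `n_grid/oversampling` "independent" frequencies proved
anti-conservative (empirical type-I ~10% at nominal 5%); the Bonferroni-
flavoured default is mildly conservative (~2–3% empirical).  A seeded
permutation mode provides an exact alternative.

Classification is by **iterative prewhitening**: locate the strongest
significant peak, subtract the least-squares *periodic waveform* at its
refined frequency (fundamental plus 2nd and 3rd harmonics — a rhythmic
component is periodic, not sinusoidal, and its harmonics leak into the
search range even from below it), and re-test the residual, up to three
components.  One component → rhythmic (τ = its period); two or more →
complex; none → arrhythmic.  Naive peak-merging cannot make this
distinction: spectral-leakage sidelobes of a strong rhythm stay
significant several hours away in period, far beyond any sensible merge
window, while genuine second components (e.g. 22 h + 27 h) must be kept.

## Rhythm statistics

*JTK-style test.*  For each (period, lag) on the grid (default period
24 h, lag step = sampling interval) the data are compared with a cosine
reference ordering via Kendall's S.  The per-combination p-value is
one-sided from the exact null of the Jonckheere–Terpstra statistic over
the reference tie groups, computed by Harding's convolution of Gaussian
binomial coefficients — exact for tie-free data at any sample size, and
fast.  Tied data fall back to a seeded permutation null.  The reported
p is the grid minimum Bonferroni-corrected by the number of combinations;
antiphase signals are caught by the opposite lag.  Empirical calibration
at the 6-timepoint × 3-replicate design: type-I ≈ 3–4% at nominal 5%,
power ≈ 1.0 at cosine amplitude = 2× noise SD.

*Circular statistics.*  Rayleigh p uses the standard exponential-series
approximation of Z = n·rho².  The two-sample Watson U² is computed from
pooled-ECDF differences evaluated after tied blocks (midrank-equivalent,
symmetric in the samples, rotation-invariant) with a seeded permutation
p-value `(1 + #{U²* ≥ U²})/(B + 1)` by default (asymptotic tail as an
option).  Grubbs' test uses the t-based critical value; an iterative
variant removes one outlier at a time.

## qPCR quantification

Efficiencies come from the dilution-series slope (E = 10^(−1/slope),
sanity-bounded to (1, 2.2]); relative expression is the efficiency-
corrected ratio E_t^ΔCq_t / E_r^ΔCq_r against a configurable calibrator
sample, with technical replicates averaged on the Cq scale first.  With
Gaussian Cq noise sd on every well and n replicates, the log2-ratio error
has standard deviation `sd·sqrt(4/n)` (four mean-Cq terms); the tests
check the estimator against exactly this propagation.  The plain
2^(−ΔΔCq) form is the special case E = 2.

## Densitometry

ROI mean gray values with local-background subtraction.  Rectangles are
specified in micrometres and converted to pixels half-open (floor of the
start edge, ceil of the end edge; sub-pixel edges not interpolated).
Negative background-corrected values are kept and flagged rather than
clamped, so group means stay unbiased.  Cell bodies are supplied as drawn
masks (or simulator ground truth); no automatic segmentation is
attempted.  Per-brain values average the two hemispheres, with a flag
when only one is available.

## Photoperiodic response and CDL

A female is diapausing iff she laid no eggs within the observation window
AND carries neither mature eggs nor vitellogenic oocytes; ovary fields
are mandatory for non-layers.  Incidence per photoperiod is fitted with
the four-parameter logistic by binomial maximum likelihood (asymptote
bounds p_min ∈ [0, 0.5], p_max ∈ [0.5, 1] for identifiability on
~11-point curves, optionally pinned at 0/1), using an analytic gradient
and a data-driven start with a small multistart fallback.  The CDL is by
default the absolute 50% crossing of the fitted curve; the midpoint
(inflection) definition is provided because the two diverge for partial
responders that never reach 100% diapause, where the 50% crossing may not
exist inside the observed range and is flagged extrapolated.  CDL
uncertainty is a seeded nonparametric bootstrap over individual females
within each photoperiod (default B = 1000), reported as SD and percentile
95% CI; cohort differences pair bootstrap replicates.  At the reference
design (30 females × 11 photoperiods of 8–18 h, slope 3/h) the median
recovery error is ~0.08 h, bootstrap SD ~0.1 h, and CI coverage ~94%.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use: 12-day constant-
condition records at 5-min bins for periodogram work (500 null agents for
type-I, 20 agents per τ for recovery, 100 cohort pairs of 16 animals for
the τ-contrast power); 5-day LD records for diel scoring (cohorts of
32–96); 200 seeds for CDL recovery and the 20-min CDL shift, 200
bootstrap-CI coverage replicates at B = 199; 1000 null and 300 signal
simulations for JTK calibration; 500 permutation-null p-values for the
Watson uniformity check.  These sizes make every stochastic check stable
at the asserted thresholds while keeping the full validation run in the
minutes range on a single CPU.

## Known limitations

* The LD peak-count rule depends on two tunables (prominence fraction,
  separation); they are exposed, and borderline bimodal animals will
  migrate between calls as they move.
* The analytic significance threshold for the periodogram is mildly
  conservative by construction; use the permutation mode when exact
  levels matter.
* The JTK exact null assumes tie-free measurements; heavily tied data use
  permutations and inherit their granularity.
* CDL confidence intervals are percentile bootstrap; for very flat
  response curves (slope ≪ 1/h) the CDL is weakly identified and the
  bootstrap widens accordingly rather than failing.
* The masking model is phenomenological (single exponential state); real
  light-adaptation dynamics may be multi-timescale.
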