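# Methods

This note documents the generative model behind the synthetic cohorts, the
exact conventions used by each analysis stage, the parameter defaults and
why they were chosen, and what the passing tests do and do not establish
about real telemetry.

## Synthetic cohort model

One animal's signal at minute t is

    s(t) = L + A_c·cos(2π t / P_c)
             + A_u(t)·cos(θ_u(t))
             + A_e·cos(2π (t − φ_e) / P_e)
             + ε(t)

- **Circadian**: amplitude `circ_amp` (A_c), period `circ_period_min`
  (P_c = 1440 min). The circadian phase is shared by all animals (a cohort
  entrained to one light cycle), which is what makes this component
  *structured across individuals* and removable by a dynamic baseline.
- **Ultradian**: carrier near `ult_period_min` (default 120 min, inside the
  1–3 h band) with circadian-modulated amplitude
  A_u(t) = `ult_amp`·(1 + `ult_mod_depth`·cos(2π t/P_c)). The carrier phase
  θ_u advances 2π·Δt/P_u per step **plus Gaussian jitter** of SD
  `ult_phase_jitter_sd` per minute — a phase random walk, the simplest
  mechanism that makes ultradian rhythms drift out of day-to-day alignment
  while leaving the circadian envelope intact. The walk's starting phase is
  a stable per-animal constant (hashed from the animal id): ultradian
  oscillators are not synchronized across animals, and keeping the constant
  seed-independent means the noise-free signal is identical across master
  seeds.
- **Estrous** (females only): a sinusoidal 4-day modulation
  (P_e = 5760 min) whose peak is centred on the animal's estrous day
  (`estrous_day_offset` ∈ 0..3, assigned round-robin in cohorts). The
  waveform is a modelling choice; only the 4-day period is constrained.
- **Noise**: ε ~ N(0, `noise_sd`²) i.i.d. per minute.
- **Activity link**: for activity the continuous signal is used as the rate
  of a per-minute Poisson draw after flooring at 0, so counts are
  nonnegative integers, zeros are genuine zeros, and counting noise scales
  with the rate as in real actimetry.

Per-animal random streams derive from `(master_seed, animal index)` via
`numpy` seed sequences, so any animal can be regenerated independently.

### Default sex profiles and their rationale

Temperature (°C): baseline 36.9 both sexes; circadian amplitude 0.8 both;
ultradian amplitude 0.40 (m) / 0.25 (f); modulation depth 0.8 / 0.4; phase
jitter 0.06 rad·min⁻¹ both; noise SD 0.35 / 0.15; estrous amplitude 0.05
(f). Activity (counts/min): baseline 12, circadian 10 both; ultradian
6.0 / 4.5; depth 0.8 / 0.4; jitter 0.06 both; noise SD 6.0 / 2.0; estrous
1.0 (f).

These magnitudes are realistic for mouse telemetry (≈1.5 °C circadian
peak-to-trough, ultradian excursions of a few tenths of a °C, low-count
bursty activity) and were calibrated so the cohort qualitatively reproduces
the orderings the analyses are designed to detect:

1. **Males carry more total variance** (`noise_sd`, `ult_amp`,
   `ult_mod_depth` all larger), so male cumulative error, band power and
   DTW distance exceed female.
2. **Males carry a lower *proportion* of structured variance**: the male
   noise-SD ratio (m:f ≈ 2.3 for temperature) exceeds the ultradian
   amplitude ratio (≈1.6), so the male day-to-day residual is relatively
   more noise-dominated. This is what makes the raw within-day
   (mean-day) error contrast male-greater: that statistic is invariant
   under joint scaling of residual and profile SD, so only the *composition*
   of the residual, not its size, can move it.
3. **Circadian structure dominates**, so the static→dynamic error reduction
   lands near one third (measured ≈44% for temperature, ≈32% for activity,
   temperature > activity).
4. **The estrous modulation is small**: it produces a female
   staggered→aligned dynamic-error reduction of ≈3–4% on average for
   temperature (≈1% for activity) with ≈0% mean change for males — the
   few-percent scale reported for real cohorts. Replicate-to-replicate
   spread of this quantity (±5 percentage points) is genuine arrangement
   noise, so the tests assert it on the replicate aggregate.

## Cleaning

Temperature: values below 35 °C are set to 35 (sensor dropouts read low),
then values beyond the individual's mean ± 3 SD — mean and SD computed on
the floored record of that individual, since cleaning precedes any pooling —
are winsorized to the 3 SD bound. Activity: winsorized above mean + 3 SD
only; zeros are never inflated. Cleaning is idempotent and
length-preserving.

## Arrangements

**Estrous alignment** circularly shifts each female by whole days so day
index 1 (0-based) is a day of estrus; males pass through untouched.
**Staggering** starts from the aligned matrix and delays row k (counted
within its sex group) by k × 1440 min, circularly within the record; with a
4-day cycle, 12 aligned females fall into 4 phase classes of 3. Males
receive the same shifts as a manipulation control. Circular shifting (rather
than truncation) preserves row lengths and value multisets; its cost is
that the wrapped 14 mod 4 = 2 days sit off-phase, a small edge effect
accepted for exact sample-count preservation.

## Error statistic and units

`error_value(x, μ, σ) = max(0, |x−μ|/σ − 1)`: the distance beyond one
comparative SD, in comparative-SD units. The absolute value implements the
reading of error as *distance* from the mean: deviations below the mean
count equally.

**Unit convention for curves.** A cumulative curve sums per-minute errors.
For a static baseline the unit is unambiguous (the pooled SD). For a
dynamic baseline, dividing each minute by its own σ_t would standardize the
residual and make dynamic error incomparable to static error (and typically
*not* smaller — the z-score distribution is unit-free). Cumulative curves
are therefore expressed in one **common unit**: the per-minute excess
distance max(0, |x−μ_t| − σ_t) in signal units, divided by a single
reference SD — the static SD of the same cohort matrix. This is the "static
SD of the population" axis convention, it reduces to `error_value` exactly
for static baselines, and it is what makes "dynamic < static whenever
structure is shared" a theorem rather than an accident.
`error_curve(..., unit_sd=None)` retains the per-minute-SD reading for
users who want standardized residual exceedances.

**Within-day (mean-day) error** compares each minute to the animal's own
per-minute-of-day mean and SD across its 14 days. The raw quantity is
summed in signal units (`unit_sd=1.0`); the normalized quantity divides by
the individual's **mean SD** — the average of its 1440 profile SDs. With
that normalizer, a pure difference in noise scale between two animals
cancels exactly, so a raw difference that survives normalization indicates
a genuine difference in residual *structure*, not just in scale. (Dividing
by the full-record SD, which is dominated by the circadian amplitude,
cannot cancel a noise-scale difference; that normalization is used for the
cohort-level summaries and for DTW.)

Degenerate SDs are floored at ε = 10⁻⁹ signal units and flagged; zero
profile SDs are routine for activity (all-zero minutes) and logged at debug
level.

## Wavelet analysis

Generalized Morse wavelet, frequency-domain form a·ω^β e^{−ω^γ} for ω > 0
(analytic), β = 5, γ = 3. Scales are chosen so the wavelet's peak frequency
ω_p = (β/γ)^{1/γ} maps to each target period on a log grid (default 30–2160
min, 16 voices/octave — bracketing both analysis bands with margin).

- **Normalization**: bandpass (peak magnitude 2 in the frequency domain), so
  a real cosine of amplitude A yields |W| ≈ A, power A², at its matching
  scale *regardless of period*. Cross-band comparisons implicitly assume
  this comparability; unit-energy normalization would instead tilt power
  by √scale across periods.
- **Boundaries**: mean subtraction then zero padding to the next power of
  two ≥ 2N; no circular wrap-around.
- **Cone of influence**: each scale's e-folding half-width is measured
  numerically from the synthesized time-domain envelope once per (β, γ) and
  scales linearly with scale. Band summaries (mean and median per-minute
  max power) exclude minutes inside the COI at all band periods; on a
  14-day record the circadian-band COI consumes roughly a day at each edge,
  and including it would bias medians toward the attenuated edges.
- **Second order**: the ultradian (1–3 h) band-power series is
  mean-subtracted (not renormalized) and transformed again; the circadian
  (23–25 h) band of that transform measures circadian modulation of
  ultradian amplitude.

Because the quantitative power values depend on these implementation
conventions, only orderings and contrasts of band power are treated as
reproducible quantities; the tests assert period recovery (within one grid
voice for noise-free sinusoids), amplitude-squared scaling, and
monotonicity of the second-order statistic in the generative modulation
depth.

## Dynamic time warping

Classic O(n·m) dynamic programming with local cost |a_i − b_j|, steps
{(1,0),(0,1),(1,1)}, and **no window constraint** — warping may span the
whole day. The full 1440 × 1440 table is evaluated by a numba kernel
(≈5 ms per day pair). Distance is the optimal path's summed local cost, in
signal units, with no path-length normalization; ties in backtracking
prefer diagonal then vertical (any optimal path is acceptable — only the
distance is consumed downstream). Day pairs are successive days of the
staggered arrangement, so female averages are not deflated by cross-female
estrous similarity. DTW is not a metric (triangle inequality can fail);
no such property is assumed. Days are not z-scored before warping, keeping
distances in signal units.

## Statistics

Rank-sum: two-sided Wilcoxon/Mann-Whitney; exact enumeration when both
groups ≤ 10 and tie-free, tie-corrected normal approximation (no continuity
correction) otherwise; reported statistic is W, the rank sum of the male
group. Kruskal-Wallis on the last hour of cumulative error supports two
poolings: all 60 terminal per-minute values per animal (the headline,
matching the very large χ² scale such pooling produces), or one per-animal
mean (`per_animal_mean=True`). The pooled variant treats autocorrelated
within-animal values as independent and is anticonservative as a
significance test (measured ≈80% null rejection); the per-animal variant is
correctly calibrated (≈5–9%) and is the one used for type-I error
validation. No multiple-testing correction is applied; the report carries
the number of contrasts (14: static/dynamic cumulative error × 2 signals,
raw/normalized within-day error × 2 signals, raw/normalized DTW × 2
signals, first/second-order band-power medians for temperature) so users
can correct as they see fit.

## Problem sizes used in validation

The full default pipeline (26 animals × 14 days × 2 signals, all stages)
runs in about a minute on one core. The replicated test batteries use
reduced records chosen as the smallest sizes at which each quantity is
well-defined and stable: 5-day cohorts for the 100-replicate
direction-recovery battery (with band-limited wavelet grids around the two
analysis bands — the band definitions are unchanged), 4-day cohorts for the
200-replicate null calibration (a 2-day record makes within-day error
degenerate: with two days every deviation is |d|/2 < SD = |d|/√2; 3-day
records leave staggering wrap artifacts in DTW), and full 14-day cohorts
for the estrous-alignment and within-day dissociation tests, where the
4-day cycle and the 14-day profile matter.

## Known limitations

- The generator is phenomenological: no thermoregulatory mechanism, torpor,
  light-cycle transitions or cage-change artifacts; sinusoidal components
  plus Gaussian/Poisson noise cannot reproduce the waveform asymmetries of
  real CBT/LA records. Passing tests establish that the *pipeline* detects
  structure it should detect and stays calibrated under a null — not that
  real mice have these parameter values.
- Wavelet power magnitudes are normalization-relative; compare only within
  one convention.
- Circular day-shifts mis-phase the wrapped days (14 mod 4 ≠ 0); effects
  are at the percent level of the alignment contrast.
- The estrous-alignment error reduction has ±5-point replicate spread at
  the default effect size; single runs should not be over-interpreted.
- DTW at 1440 samples/day is exact but O(n²); records at finer than 1-min
  resolution would need banding or downsampling, which would change the
  "no boundary" semantics.
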