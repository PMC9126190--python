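# Methods

`cbtrhythms` analyses continuous (1-min binned) core body temperature (CBT)
from adolescent female rats at three timescales — ultradian (1–3 h), circadian
(23–25 h) and ovulatory (the 4-day estrous cycle) — and relates them to daily
fecal estradiol (fE2). This note records the models, the numerical choices,
and what the synthetic test bed does and does not establish.

## Preprocessing

Telemetry records carry transmission spikes, near-instantaneous jumps and
dropouts. Cleaning applies three rules in a fixed order:

1. **Outliers.** Samples more than `outlier_sd` (default 4) whole-record SDs
   from the whole-record mean are replaced by the median of the non-missing
   samples in the preceding `replace_window_min` (default 60) minutes. The
   reference mean/SD are computed once on the raw record, not rolling: a
   rolling reference would re-flag its own replacements, and one pass is then
   idempotent.
2. **Jumps.** Samples whose first difference exceeds `jump_cutoff` per 1-min
   step are replaced the same way. The default cutoff of 1e5 is deliberately
   inert for data in °C; it exists because logger units vary, and it is
   exposed in the configuration.
3. **Gaps.** Missing runs of at most `max_gap_min` (default 10) minutes are
   linearly interpolated between their bounding observations; longer runs —
   and runs touching a record end — stay missing and are counted.

If the preceding window of a replacement target is empty, the nearest
preceding value is used (with a warning); only a target with nothing before
it at all falls back, loudly, to the overall median. Postnatal day *d* spans
ages [d, d+1); the adolescent record splits into three equal half-open phases
— p26–p41, p42–p58, p59–p74 — used by the phase-wise trend tests.

## Morse wavelet band power

The spectral engine is a continuous transform with the generalized Morse
wavelet, Ψ(ω) ∝ ω^β exp(−ω^γ) for ω > 0, with defaults γ = 3, β = 5 — a
compact analytic wavelet suited to slowly drifting circadian/ultradian
components. Scales lie on a logarithmic period grid, 16 voices per octave
from 1 h to 39 h; power is the squared coefficient modulus.

**Normalization.** Filters are L1/bandpass normalized (peak filter value 2 at
every scale). Two properties follow: the response modulus to a pure tone of
amplitude A is ≈ A at the matching scale, and the scale of maximal tone
response coincides *exactly* with the analytic peak mapping
ω_p = (β/γ)^(1/γ) — a property the test suite verifies for β ∈ 3…8,
γ ∈ 2…5. Under L2 (unit-energy) normalization the tone-response peak is
biased by ((β+½)/β)^(1/γ) (about 1.8 voices at β=3, γ=2), so band
attributions near band edges would depend on the envelope parameters. L1 is
also the convention of the MATLAB wavelet tooling this field predominantly
uses, which keeps power surfaces comparable across implementations. Absolute
power units are arbitrary; every cross-animal comparison is rank-based or
z-scored.

**Edges.** The default mask is a cone of influence at the e-folding
half-width of the wavelet envelope, measured numerically once per (β, γ) at a
reference scale and scaled linearly with period (≈ 0.89 periods for the
default pair, i.e. ~21 h at the circadian scale). A fixed one-day trim is
available as the alternative policy; with recording from p25 either way the
analysis span is p26–p74. The transform zero-pads past the longest wavelet
support, so wraparound never reaches the valid region.

Band series are the per-minute *maximum* power across grid periods inside a
band — circadian 23–25 h, ultradian 1–3 h — smoothed by a centred 24 h moving
mean (edge-truncated, invalid samples excluded), optionally z-scored against
a reference interval (default: the whole record; the normalization entering
the fE2 regression is flagged configurable because no single convention is
standard). Restricting the transform to the scales inside one band is exact —
band-max only ever consults those scales — and is used by the Monte-Carlo
suites for speed.

**Crossing criterion.** The timing of the circadian power rise is the first
postnatal day the smoothed daily series exceeds mean + 2 SD of a reference
window, default p26–p29. The reference must be a pre-rise baseline: if the
reference window sits on the rising limb itself, threshold and trajectory
rise together and the crossing day becomes independent of ramp slope (see the
generator's ramp timing below).

## Estrous cycle detection and ovulatory metrics

* **Rise day.** First day fE2 exceeds baseline mean + 2 SD, with the baseline
  window p25–p30 (before vaginal opening). A single "starting value" supplies
  no SD, so a window is required; its sample SD (ddof 1) is used. Zero
  baseline SD with no exceedance is reported as an undefined threshold, not
  as "no rise".
* **Alignment.** From the rise day, consecutive 4-day blocks are anchored so
  the within-block fE2 maximum sits at day 3 (fE2 rises for three days, falls
  on the fourth). Ties go to the earliest day; labels propagate arithmetically
  through unobserved collection gaps; blocks with a missing day are flagged
  incomplete and dropped from per-block statistics. Five-day blocks exist only
  as a sensitivity analysis.
* **Combined metric.** Per day and animal, z(mean CBT) − z(median ultradian
  power), z-scored per animal over the analysed span. The ultradian daily
  medians are taken on the *raw* band-max power: its wavelet support is
  under ~3 h, so daily medians are day-local and the cycles entering the
  Friedman replication stay independent. A 24 h-centred smoother would mix
  adjacent days and correlate values across block boundaries (inflating the
  test's size); smoothing is therefore reserved for the slow circadian
  series (trends, crossing times), where it is part of the procedure.
  The metric is large when temperature
  is high and ultradian power low — the peri-ovulatory signature. It is
  invariant to affine rescaling of either input, and within-block Friedman
  ranking makes the day-of-cycle test additionally insensitive to slow trends.
* **Day-of-cycle test.** Each complete block (one cycle of one animal) is one
  Friedman block with the four day-of-cycle conditions — cycles are treated
  as independent replicates — followed by Dunn z-tests on within-block rank
  sums, Holm-adjusted (Bonferroni available). Animals without a detected rise
  (or with a rise too near the record end to anchor) are binned from a fixed
  fallback anchor, p32, the midpoint of the onset range; under the null any
  anchor is equivalent.
* **Multi-day spectrum.** Daily mean CBT is linearly detrended and Fourier
  transformed (no taper, one-sided magnitude, 2/n scaling); the 4–5 day
  band area is the trapezoid over frequency between 1/5 and 1/4 cycles/day
  with interpolated endpoints, making areas exactly additive over disjoint
  sub-bands. Spans shorter than three times the longest band period are
  rejected. Per-cycle fE2 AUC is the trapezoid over each complete block at
  one-day spacing.

## Statistics

Two-group comparisons use the two-sided Mann-Whitney U; three or more
independent groups use Kruskal-Wallis with the χ² approximation; repeated
designs use Friedman. Dunn's post hoc z-tests (pooled mean ranks with tie
correction for KW; within-block rank sums for Friedman) are Holm-adjusted by
default — Holm dominates Bonferroni at identical error control. Monotone
trends use Mann-Kendall with tie-corrected variance and continuity
correction; tau is tau-b. Minute series are thinned to one point per hour for
spans under 3 days and one per day otherwise (exactly 3 days → daily). The
fE2 relation is a linear mixed model, normalized daily circadian power ~ 1 +
fE2 with correlated random intercept and slope per animal, fitted by maximum
likelihood so AICs are comparable across fixed-effect structures; singular
random-slope fits fall back to a random intercept with a flag. Reported R² is
marginal (fixed-effect variance over fixed + random + residual).

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes, per
hormonal group, with a ground-truth record of every drawn quantity:

* CBT (°C, 1-min) = baseline 37.0 + pubertal ramp (0.02 °C/day over p26–p41)
  + circadian sinusoid phase-locked to the light cycle (peak mid-scotophase;
  lights on 01:00, off 13:00) + ultradian 2-h sinusoid (amplitude 0.15 °C,
  with 20% iid daily amplitude jitter) + AR(1) noise (stationary SD 0.1 °C,
  lag-1 coefficient 0.9 at 1 min — the minimal autocorrelated noise model for
  physiological temperature) + iid daily level offsets (SD 0.08 °C).
  The day-scale components matter for calibration: without them, daily mean
  CBT is almost deterministic (the daily mean of the fast noise has SD
  ~0.01 °C), any slow trend then orders the days within every 4-day block the
  same way, and the day-of-cycle test rejects far above its nominal level on
  acyclic animals. Real daily mean CBT varies by several hundredths of a
  degree from day to day with behavioural and metabolic state.
* The circadian amplitude ramps linearly 0.15 → 0.5 °C across
  `circadian_ramp_window`, default p31–p41, then stays constant. The ramp
  starts at p31 because the circadian elevation follows the pubertal fE2 rise
  (typically p31–p36); p26–p29 is therefore a pre-rise baseline in every
  group, which is what makes the 2-SD crossing measure rise *timing*.
* fE2 (pg/ml, daily) = baseline 10 ± 1 (Gaussian); from an onset day drawn
  uniformly in p31–p36, the relative profile [1, 2, 3, 0.5] × 8 pg/ml repeats
  every 4 days (three rising days, one falling; peak = cycle day 3). On cycle
  day 4 (the day after the fE2 peak) CBT is elevated by 0.25 °C and ultradian
  amplitude suppressed by 40% — the programmed ovulatory modulation.
* Group templates — **Intact**: as above. **IntactC**: identical until p50;
  from the contraceptive window (p50–p58) onward estrous modulation of fE2,
  CBT and UR is removed permanently, CBT drops 0.2 °C and circadian amplitude
  0.15 °C (no recovery law is invented); tonic fE2 level is preserved so only
  the patterning disappears. **OVX**: no cycles, circadian plateau 0.3 °C,
  CBT declines 0.03 °C/day from p59. **OVX_E2**: no cycles, circadian ramp
  runs p29–p36 — steeper, starting at capsule implantation — and CBT is
  maintained. No quantitative effect sizes are reported for the
  contraceptive temperature depression; those defaults are free parameters
  of the simulator, not estimates.
* Artifact injection adds spikes (> 4 series SDs by construction, so the
  despiking rule can see them) and short/long missing runs; event counts are
  `round(rate × record days)` so tests can assert exact counts, with seeded
  positions.

Per-animal seeds derive deterministically from the master seed
(`SeedSequence.spawn`), so identical inputs reproduce byte-identical cohorts.

**What passing tests show — and what they do not.** The generator's
components are additive sinusoids with stationary AR(1) noise plus iid
day-scale jitter; real CBT has waveform asymmetry (square-ish scotophase
plateaus), activity-driven transients, autocorrelated multi-day baseline
drifts and occasional 5-day cycles, none of which are emulated. Recovery results therefore demonstrate that the pipeline
detects the programmed structure at realistic effect sizes and controls false
positives under the programmed null — not that real recordings meet these
assumptions.

## Problem sizes used by the test suite

Monte-Carlo suites run at: 100 ramped + 100 flat animals for trend recovery
(records p25–p43; the scored window is p26–p41); 100 Intact + 100 OVX cohorts
of n=8 for ovulatory recovery (full p25–p75 records), with the 5-day-rebin
control on 40 of the Intact cohorts; 100 cohort draws of 8 vs 8 for the
post-p50 spectral contrast; 50 paired seeds for crossing-time ordering; 200
replicates (8 animals × 20 days) for mixed-model slope recovery. Band-limited
transforms (exact restrictions of the default grid) keep these loops cheap.

## Known limitations

* The cone of influence uses the e-folding of the envelope; energy outside
  the cone is small but not zero, so shift-covariance holds only to a few
  percent near the cone boundary.
* Day-of-cycle inference assumes the arithmetic 4-day labelling stays in
  phase across unobserved spans; animals with irregular cycle lengths would
  progressively misalign.
* The mixed model assumes a linear power–fE2 relation on the z scale; the
  marginal R² convention understates variance explained when random slopes
  are large.
* `HormoneSeries` requires non-negative concentrations; assay values below
  the detection limit should be truncated to zero upstream.
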