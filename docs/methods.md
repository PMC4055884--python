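# Methods

`tailflip` models and analyses a short-term behavioural nociception assay in
adult zebrafish: individual fish are recorded in small chambers by an
impedance biosensor whose processed output counts *tail-flips per minute*, a
noxious stimulus (dilute acetic acid injected into the lips) suppresses
locomotion, morphine attenuates that suppression, and naloxone blocks the
morphine effect.  The raw recordings behind the assay are not publicly
available, so the package pairs every analysis stage with a ground-truthed
generator that reproduces the statistical structure the analysis assumes.
This note documents the model, its parameters and the numerical choices.

## 1. Behavioural generator

### Burst point process

Zebrafish swim in *bursts* of consecutive tail-flips.  The generator realizes,
for each fish and recording phase:

- burst initiations from an inhomogeneous Poisson process with rate
  `baseline_burst_rate × m(t) × G × L(t)` (bursts/min), where `m(t)` is the
  deterministic acclimation/effect modulation, `G` a fish-level gain and
  `L(t)` a per-minute lognormal noise multiplier (all mean 1);
- burst sizes `F = 1 + Poisson(flips_per_burst_mean − 1)` flips;
- within-burst inter-flip intervals uniform on 0.2–0.5 s, i.e. an
  instantaneous rate of 2–5 flips/s, the species' characteristic pattern;
- **serialization**: a fish has one tail, so bursts cannot overlap.  Bursts
  are queued — a burst whose sampled start falls inside the previous burst is
  delayed until that burst ends plus a 0.3 s inter-burst pause.  Without
  serialization roughly 40% of inter-event gaps fall below any physically
  sensible detector refractory and the event stream stops being resolvable,
  which no real single-animal recording exhibits.

A Poisson-thinned *geometric* burst size was considered and rejected: its
coefficient of variation (~0.9 at mean 6) makes per-minute counts so
overdispersed that the assay's published design guidance (about 20 fish per
group for a 10-point difference, below) cannot be reproduced at any burst
rate compatible with serialized bursts.  The shifted-Poisson size (cv ≈ 0.37)
matches both.

The series-level path (`minute_count_matrix`) draws per-minute flip counts
directly from the identical compound distribution (`B + Poisson(B·(mean−1))`
given `B ~ Poisson(rate)`), so detector-bypassing simulations and
event-level simulations share one model.  Counts attribute a burst's flips
to the minute the burst starts in; at the default burst length (~2 s) the
cross-minute spill is negligible.

### Fish-level heterogeneity and time structure

Each fish draws once, and keeps across phases:

| parameter | meaning | default |
|---|---|---|
| `G` | lognormal activity gain (between-fish spread of absolute activity) | cv 0.5 |
| `A` | acclimation amplitude `acclimation_trend × lognormal` | trend 0.6, cv 0.5 |
| `R` | lognormal post-treatment response multiplier (day-to-day state) | cv 0.05 |

During the 60-min baseline the activity factor is `1 + A·exp(−t/τ)` with
τ = 12 min: fish are elevated early and settle.  The per-minute noise cv is
inflated by a factor decaying with the same τ (`early_noise_inflation`,
default 2.0), reproducing the observed early-baseline heteroscedasticity.
Post-injection the factor is `R × effect(t)` where `effect` is a logistic
onset (midpoint 10 min after injection, scale 4 min) to a treatment-specific
asymptote, optionally with a late linear drift (used for the low morphine
dose, whose separation from the high dose only appears late in the
recording).  Default asymptotes: saline lip injection 0.85, 5% acid 0.62,
10% acid 0.45, morphine 6 mg/kg + acid 0.70, morphine 3 mg/kg + acid 0.70
with −0.003/min after 60 min, morphine + naloxone + acid 0.50, handling
controls 0.90–0.95.

### Calibration of the defaults

The generator's defaults are the package's definition of "a typical study".
They were fixed once, by matching four anchors the assay reports, and are
not tuned per run:

1. the Winsorized mean of normalized activity over the first 40 baseline
   minutes sits ≈ 20% above the stable level (the settling decline);
2. the Winsorized SE across fish is ≈ 6× larger in the first 5-min bin than
   in the stable window;
3. the rank-based pairwise test reaches 80% power for a sustained
   10-percentage-point difference at ≈ 20 fish per group;
4. the morphine(6 mg/kg)+acid group ends the recording near 70% of baseline.

Anchor 1 fixes (`acclimation_trend`, τ) — note that the *estimated* decline
exceeds the raw trend integral by ~4 points because each fish's divisor (its
stable-window median of noisy counts) is itself estimated; the calibration
uses the estimator, not the integral.  Anchor 2 fixes `early_noise_inflation`
and the trend-amplitude cv.  Anchor 3 fixes the per-minute variance budget
(burst rate 15/min, within-fish cv 0.15): the dominant error source in a
normalized endpoint is the baseline-median estimate (~9% per fish), shared
across all of a fish's bins — which is exactly why the inference stage must
model within-fish covariance.  Anchor 4 is the morphine effect asymptote.

### Measurement channel

`render_trace` turns an event train into the demodulated 100 Hz biosensor
signal: each flip stamps a biphasic transient (one sine cycle, 40 ms — its
spectral content reaches the 20+ Hz needed to resolve sharp edges), plus
white noise (sd 0.1 per unit kernel amplitude), a slow sinusoidal
multiplicative gain drift (±30%, 10-min period, random phase) and sporadic
single-sample artifacts (0.5/min, ~4× kernel amplitude).  Ground truth is
never altered by measurement parameters.  The video arm is modelled as a
correlated random walk in a 9 cm × 8 cm arena with step length proportional
to the activity factor, sampled at 10 fps (600 frames/min), with reflecting
walls.

## 2. Event detection

The detection chain mirrors the biosensor's processing: zero-phase band-pass
0.2–40 Hz (Butterworth high-pass order 4 at 0.2 Hz and low-pass order 8 at
40 Hz, applied forward-backward so event times are not shifted), automatic
gain control (running robust scale over 10-s blocks, linearly interpolated,
with the quiet-block scale floored at 10% of the median active scale so
silence is not amplified into ringing), then sharpness detection: local
maxima of the first-difference magnitude exceeding
`max(4 × local MAD-scale of the signed derivative, 8% of the trace's 99.9th
sharpness percentile)`, separated by a 0.15 s refractory (just below the
0.2 s minimum credible inter-flip interval).  Finally, a burst-context rule
implements false-positive rejection: an accepted event needs at least one
other candidate within ±1 s, because genuine swimming comes in multi-flip
bursts; isolated spike artifacts are dropped.

Numerical notes: the MAD scale must be computed on the *signed* derivative —
the rectified sharpness is half-normal and its MAD underestimates the spread
several-fold.  The relative sharpness floor handles the noise-free limit,
where the local scale degenerates and the band-pass filter's ~2–5% ringing
sidelobes would otherwise cross any purely scale-relative threshold.
At the defaults the detector achieves per-fish recall and precision ≥ 0.99
across activity levels and accepts no events on noise-plus-artifact-only
traces; detected counts track the generator's activity factor with Spearman
ρ > 0.9.

The detector's accuracy has no published benchmark to compare against, so
its acceptance is property-based against the generator's ground truth.

## 3. Normalization and summaries

Activity levels differ widely between fish, so all analysis is within-fish:
each fish's post-treatment per-minute values are divided by the **median of
its stable pre-treatment window** — by default the last 20 min of the 60-min
baseline, where activity has settled — and expressed in percent.  (The
assay's own description uses the last 20 min in the text and the last 25 min
in a figure caption, and reports both N = 26 and N = 27 for that cohort; the
package defaults to 20 min and exposes it as configuration.)  Fish with a
non-positive baseline median or incomplete recordings are excluded and
logged, mirroring the assay's tested-versus-analysed counts.  Normalized
minutes are averaged into recording periods (15 min sensor, 10 min video)
timestamped by their start relative to injection; the 30-min anaesthesia
recovery gap is not recorded, and a trailing partial bin (the 80-min
recording leaves 5 min at 15-min bins) is dropped and logged.

Group summaries are **20% Winsorized means with standard errors**: with
γ = 0.10 per tail and `g = floor(γn)`, the `g` smallest values are replaced
by the (g+1)-th smallest and likewise at the top, and
`se = s_w / ((1 − 2g/n)·√n)` with `s_w` the winsorized sample SD
(Tukey–McLaughlin form; the assay cites the estimator without a formula, and
this is its standard companion, reducing to `s/√n` at γ = 0).  At the
assay's group sizes (6–14) `g` is 0 or 1, which the floor rule makes
explicit so plotted error bars are reproducible.

## 4. Rank-based longitudinal inference

Treatment and time effects are tested with a nonparametric marginal model
for factorial longitudinal designs.  All `N` observations are pooled and
mid-ranked; each (group, period) cell gets a relative treatment effect
`p̂ = (mean cell mid-rank − ½)/N ∈ (0,1)`; in a balanced complete design the
unweighted cell average is exactly ½.  Hypotheses (group main effect, time
main effect, group × time interaction) are tested with the ANOVA-type
statistic `F = n·p̂′Tp̂ / tr(TV̂)` where `T` is the projection for the effect
and `V̂` the block-diagonal estimate of the covariance of the per-fish rank
vectors — this is where within-fish dependence across periods (dominated by
the shared baseline-median error) enters.  `F` is referred to an F
distribution with Box-type moment-matched degrees of freedom
(`df1 = tr(TV̂)²/tr((TV̂)²)`; for the between-fish group effect a finite
`df2` from the per-group covariance blocks, for within-fish effects
`df2 = ∞`).  The procedure is invariant under strictly monotone
transformations of the data and needs at least 2 (recommended ≥ 4) fish per
group; incomplete fish are removed per complete-case analysis rather than
imputed.

Validation: type-I error 0.044–0.061 across designs at α = 0.05 (Monte
Carlo, 1000 replicates, within the 0.03–0.07 acceptance band); accept/reject
decisions agree with an *exact* label-permutation oracle in ≥ 95% of small
(4 fish/group, 3 bins) datasets — with 8 fish the permutation distribution
has only C(8,4) = 70 atoms, so exact enumeration replaces a 10,000-draw
Monte-Carlo version of the same oracle; in the single-period case the group
test reduces to a two-sample rank test and agrees with
`scipy.stats.brunnermunzel`.  Pairwise group contrasts are reported
unadjusted (as the assay reports them); Holm adjustment is available.

## 5. Power analysis

Power is estimated by simulation of the full series-level chain: two groups
(control at 100%, treatment at a sustained `delta` percentage points lower),
baseline normalization, 15-min binning, pairwise rank test at α = 0.05.
`minimal_n` scans an ascending grid (default 5–30 fish/group, 500 replicates
per point), smooths the Monte-Carlo curve isotonically, and returns the
smallest n whose smoothed power reaches the target (0.80 — the assay calls
only for "sufficient" power, so the conventional value is used and exposed
as configuration).  "10% response difference" is interpreted as 10
percentage points of normalized activity sustained across all post bins.
Estimates with fewer than 100 replicates are flagged low-precision.
The detector is bypassed here: normalization cancels its (constant ≥ 0.99)
recall, and series-level replicates keep 3000 test evaluations inside
seconds rather than hours.

## 6. Reproducibility and problem sizes

Every generator accepts a seed or `numpy` Generator; studies use
hierarchical `SeedSequence` spawning (study → group → fish) so adding a
group leaves earlier fish untouched, and pipeline reruns with the same
config are byte-identical (outputs carry a config hash, the seed and the
package version).  The shipped characterization analyses use the assay's
own problem sizes: 27-fish baseline cohorts averaged over 20 replicate
studies; 9 morphine+acid fish through the full trace→detect→normalize chain,
20 replicates; power grids of 6 sample sizes × 500 replicates.  On one CPU
the whole characterization runs in about a minute.

## 7. What the synthetic data do and do not show

The generator reproduces the structure the analysis relies on — burst-shaped
events, heavy between-fish gain spread, early-baseline settling and
heteroscedasticity, multiplicative treatment effects with onset, gain drift
and artifacts in the channel — so passing tests demonstrate that the
pipeline recovers known truth under realistic variability.  It does not
model swimming biomechanics, anaesthesia-recovery physiology,
pharmacokinetics beyond the effect curves, inter-day batch effects, or
freezing/startle behaviours; conclusions about those aspects of real
recordings are outside what these tests can certify.  The video-arm
trajectory model is kinematic only, and its movie schedule is configurable
rather than fixed, since published descriptions of such schedules are often
ambiguous.
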