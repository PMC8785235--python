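# Methods and design notes

This note records the modelling assumptions, parameter choices and
numerical decisions behind larvaphen, in the spirit of a statistical
methods appendix. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

A locomotion trace is a per-subject sequence of distance-moved values
(mm) in fixed-width time bins. Throughout the package bins are half-open
intervals `[start, start + width)` with 0-based start times in seconds
from assay start. Tracking dropouts are carried as NaN, excluded from
sums, means and SDs, and never imputed — imputation would bias the
pooled-SD responder thresholds, which is the one place missingness
interacts with inference. Re-binning sums distances within coarser bins
and marks a coarse bin missing if any constituent bin is missing, so
total non-missing distance is conserved exactly; slicing follows the same
half-open convention. Distances are fixed to millimetres at ingest (the
reader's schema config supplies a unit multiplier), and the canonical
input is a single tidy long table; vendor exports are adapted by column
mapping rather than by dialect-specific parsers. The canonical format
assumes distance *per bin*, not cumulative distance.

## Assay schedules

Five presets encode the supported designs: FLD
(10/10/10/1/10 min dark/light alternation, 2460 s), startle (1-min
baseline + 25 taps at 2-s inter-stimulus intervals, 2-s event windows),
social (30 min acclimation + 15 min experimental), circadian
(3 h light / 54 h dark / 2 h light = 59 h) and dusk/dawn
(3 h light / 46 min dusk / 10 h dark / 46 min dawn / 2 h light = 16.53 h).

The dusk/dawn ramps carry two durations on purpose. The stepwise
profile — down 5% every 2 min to 5%, then 1% every 2 min to off,
mirrored at dawn — enumerates to 19 + 5 = 24 steps of 2 min = 48 min,
while the schedule's stated segment duration is 46 min. The segment
keeps the stated 46 min (so regime totals match the design as stated)
and `build_ramp` reports the enumerated 48 min; the CLI surfaces the
discrepancy whenever a ramp session is analyzed. Step timing is
asymmetric by construction: dusk holds each level and steps at interval
*ends* (the ramp starts at 100%), dawn steps at interval *starts* (the
light leaves 0% immediately). This makes dawn(t) = dusk(D − t) exact
everywhere except at the step edges themselves, where half-open
conventions differ on a measure-zero set.

## Generative model (synthetic_data)

No distributional description of per-bin distance is available for real
exports, so the simulator commits to an explicit law chosen for three
properties the analyses rely on: non-negativity, continuous values and
tunable overdispersion. Each bin's distance is gamma with mean
`rate(t) × bin_width` and squared coefficient of variation `dispersion`
(default 0.2; gamma shape = 1/dispersion), with

```
rate(t) = base_rate × condition multiplier × exp(u_subject)
          × light modulation × circadian modulation
```

* `base_rate` defaults to 1 mm/s, a realistic dark-phase locomotion rate
  for 5-dpf larvae at 1-s bins.
* Subject effects are lognormal on the rate with log-scale SD
  `sigma_subject` (default 0.2) and mean correction −σ²/2, so
  `E[exp(u)] = 1` and `base_rate` is the population-mean rate exactly;
  this makes the analytic mean identity `E[bin] = λ · bw · modulation`
  testable without lognormal correction factors.
* Light scales the rate by `light_multiplier` (default 0.6: larvae move
  less in light), interpolated linearly in intensity during ramps.
* A dark→light transition suppresses the rate to `freeze_depth`
  (default 0.2) of its value, recovering linearly at `recovery_slope`
  (default 0.002 per second, i.e. full recovery in ~400 s) — freezing
  with linear recovery, matching the linear slope analyses downstream.
* A light→dark transition multiplies the rate by
  `1 + startle_amplitude · exp(−Δt/startle_tau)` (defaults 1.5 and 20 s),
  the dark-startle burst.
* Circadian modulation is `1 + A·cos(2π(t−phase)/P)` with A = 0.4 and
  P = 24 h by default, applied in free-running sessions.
* Tap responses are Bernoulli with per-tap probability interpolated
  geometrically from `p_first` to `p_last`; an elicited response adds a
  burst of `tap_magnitude` (8 mm) spread over the 2-s window, *on top of*
  baseline movement — required for the threshold rule to remain
  meaningful.
* Social sessions draw each subject bold with probability `p_bold`;
  occupancy fractions per 15-min bin come from softmax of noisy logits
  (noise SD 0.4), and during the experimental phase bold subjects' far
  -zone logit (non-bold subjects' stimulus-zone logit) is shifted by 2.0.
  Under these defaults the SPI-based bold call disagrees with the drawn
  label in well under 1% of subjects.

Per-subject random streams are seeded from
`(master seed, CRC-32 of subject id)`, so enlarging a plate or adding a
condition never changes existing subjects' traces.

### Control calibration

The shipped control configuration targets three published control-cohort
percentages: 88% of fish responding to the first tap, 13% to the 25th,
and 59.72% bold. Since the 8-mm burst always clears the pooled
mean + 2 SD threshold (detection probability 1 under the defaults), the
expected *classified* responder fraction at tap t is
`p_t + (1 − p_t)·fp`, where fp is the probability that a tap window of
pure baseline movement exceeds the threshold. fp is computed analytically
(`threshold_false_positive_rate`): the window mean of two gamma bins is
Gamma(2/φ)-distributed given the subject effect, and the exceedance
probability is marginalized over the lognormal effect by quadrature
(≈ 1.74% at the defaults). The shipped endpoints invert this mapping,
giving generative p₁ = 0.8779 and p₂₅ = 0.1146. The bold probability is
set to the target fraction directly, since SPI misclassification is
negligible.

### What the simulator does not emulate

Real tracking data have features the generator deliberately omits:
autocorrelated burst-and-glide swim kinematics within bins, wall
preference and well-edge artifacts, tracking noise correlated with
movement speed, inter-plate and time-of-day batch effects, and any
pharmacokinetics of drug exposure (conditions differ only through the
interpretable multipliers). Passing calibration tests therefore
demonstrates that the *analysis chain* is correct and well-calibrated
under a plausible generative law — not that the law is a validated model
of larval behavior.

## Statistical core

**Mixed models.** Condition and condition × time models use a random
intercept per fish. REML estimates are reported; omnibus condition tests
are likelihood-ratio tests between ML fits with a chi-squared reference,
as in the lme4 + chi-squared workflow common in this assay literature.
The ML log-likelihoods are computed by profiling the fixed effects and
residual variance out in closed form and maximizing over the
between/within variance ratio in one dimension. This is numerically
stable when the variance component sits at its zero boundary, where
Hessian-based ML fitting breaks down; a boundary estimate is reported
with a singular-fit flag, not an error. Noise-free inputs (exact lines in
tests) degenerate gracefully to OLS with a flag. Treatment coding uses
the control level as reference, so interaction coefficients read as
treated-minus-control slope differences.

**Beta regression.** Proportion responses are modeled by ML beta
regression (logit mean link, constant precision). Responses must lie
strictly inside (0, 1); upstream code applies the Smithson–Verkuilen
compression `y′ = (y(n−1) + ½)/n` with n = the number of observations
behind each proportion. Nested-model comparisons use the likelihood-ratio
statistic referred to F(df, n − k) rather than chi-squared: at the
sample sizes proportion models see here (tens of observations) the
asymptotic chi-squared reference is markedly anticonservative (~9%
type-I error at α = 5% with n = 24 in simulation, even on exactly
beta-distributed data), while the F reference is calibrated (4.9% over
1000 null replicates).

**Multiplicity.** All pairwise condition (or slope) contrasts are
adjusted single-step using the distribution of the maximum absolute z
over the contrast family under a multivariate normal with the estimated
contrast correlation — the single-step method of the multcomp tradition.
The max-|z| tail is evaluated by a seeded antithetic Monte-Carlo sample
(200k draws), making adjusted p-values deterministic for a fixed seed and
valid for degenerate (rank-deficient) contrast families. Adjusted
p-values are floored at the unadjusted ones. A normal (z) reference is
used rather than finite-sample degrees of freedom; with the per-bin
sample sizes involved the difference is negligible, and the choice is
recorded here.

## Assay-specific decisions

**Startle ratio.** The raw ratio d20/d60 (distance in the 20 s after the
light→dark transition over distance during the 1-min light event, both
window totals) can exceed 1, so the analyzed quantity is the compressed
ratio q = d20/(d20 + d60) ∈ [0, 1], pushed off the boundary by the
Smithson–Verkuilen transform before beta regression. The raw ratio is
reported alongside. Subjects with d20 + d60 = 0 are flagged and excluded
from the regression, never silently dropped. The 20-s window is
`[transition, transition + 20)` under the half-open convention.

**Responder thresholds.** "Mean + 2 SD" is read as two *sample* standard
deviations of the per-second baseline distances pooled across all
subjects of a condition — not standard errors, which would shrink the
threshold with sample size and make per-fish exceedance calls
sample-size-dependent; and not per-fish thresholds, since thresholds are
defined per condition. Event comparison uses the mean per-second rate in
the 2-s window against the per-second threshold with a strict inequality
(a rate exactly at threshold is a non-response). Thresholds are
recomputed per session. A condition must contribute at least 10
non-missing baseline bins.

**Period locomotion model.** The condition model for an FLD period is
fitted on per-bin distances (default 10-s bins) with the fish random
intercept, since a random effect per fish is unidentifiable on one
summary row per fish. Recovery slopes are reported in mm per analysis
bin per second with the bin width recorded, because the slope's units
are otherwise ambiguous.

**SPI orientation.** SPI is the occupancy contrast of the two arena
end-thirds, normalized to [−1, 1], middle-zone time excluded from both
numerator and denominator (whether the original index includes it is not
determinable; exclusion is flagged here as the package's choice). The
default orientation is away-positive, making "bold iff r > 0" consistent
with bold fish spending more time away from the stimuli; an orientation
switch flips it for approach-positive conventions. During acclimation no
stimulus fish are present: the "social side" is the side that will later
hold them. r = 0 is classified not-bold. Bold fractions carry exact
Clopper–Pearson intervals and a Fisher (2×2) or chi-squared homogeneity
test across conditions.

**Periodogram.** The least-squares periodogram is implemented natively
in the classic tau-shifted Lomb–Scargle form (it agrees with
`scipy.signal.lombscargle` to machine precision, which the tests use as
an independent oracle) because the vectorized basis lets all permutation
replicates be scored by one matrix product. The series is linearly
detrended first, absorbing the slow activity decline over 54 h of
darkness. Significance uses ≥ 999 circular-shift permutations of the
detrended series — shifts preserve the marginal distribution and
autocorrelation shape while destroying phase alignment — with
p = (1 + #{peak ≥ observed})/(B + 1), bounded below by 1/(B+1). The
default search band is 16–32 h on an even frequency grid of 400 points;
the trace must span at least twice the band minimum. The cosinor
(mesor + amplitude + acrophase) is refitted by OLS at the dominant
period. Period estimates on 54-h spans carry an intrinsic resolution
limit of roughly ±0.5 h near 24 h (≈ 2.25 cycles observed).

## Problem sizes in the shipped checks

The test suite's calibration checks use 400 null replicates at
12 subjects/condition for the four omnibus tests, 20 replicate seeds for
parameter-recovery checks (recovery slope, responder endpoints, circadian
period at one subject per replicate, random-intercept SD), and 100 random
instances per brute-force oracle comparison. The acceptance script
averages 50 replicate cohorts of 48 (startle) and 72 (social) control
subjects. These sizes give Monte-Carlo error comfortably inside each
check's tolerance while keeping the default run quick on a laptop.

## Known limitations

* Random intercepts only; random slopes are out of scope.
* Beta regression assumes constant precision across conditions.
* The permutation p-value is per-trace; no multi-subject pooling of
  periodogram evidence beyond summarizing per-subject estimates.
* The simulator's gamma law is a modelling commitment, not an empirical
  claim about tracker output.
* Whether ramp intensity percentages are linear in irradiance is
  unknown; the light modulation treats them as linear.
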