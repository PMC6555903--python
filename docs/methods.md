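# Methods

This note documents the statistical procedures `mwtraj` implements, the
generative model behind its synthetic cohorts, the numerical conventions,
and the design choices that were genuinely open.

## Data model and exclusions

A probe table holds one row per experience-sampling prompt: participant,
response timestamp (minute resolution), mental-state label (focused, mind
wandering with or without a task, declined, invalid), a number-of-thoughts
report (NoT, integer 0–10 with the open "10+" menu item encoded at its
floor of 10, preserving ordinality without inventing mass above 10), a
five-level scene-closeness rating, and two per-probe flags (alcohol or
other substances; display problems during the rating task).  Each
participant declares a 12-h daily probing window starting at 9, 10, 11,
or 12 o'clock; the window travels with the data as a CSV column because
the event-locked analysis needs it.

Exclusion order: (1) participants with fewer than 40 *answered* probes are
removed entirely — declined and invalid probes do not count toward the
threshold, the most literal reading of a response-count criterion, and the
exclusion report records this convention so a rerun with a different
reading is easy to compare; (2) invalid records are dropped; (3) remaining
flagged records are dropped individually.  Declined probes are retained
but never analyzable.  The operation is idempotent.

Cohort proportions are computed per participant over their usable probes
and then averaged *across participants* (unweighted), so heavy responders
do not dominate; the same convention (participants as the unit) recurs in
every grand average below.

## R scores and state comparison

Ratings map monotonically to R = −2…+2 with 0 the veridical "same"
response.  Non-zero R indicates a top-down bias, read as deliberate-
constraint (cognitive-control) strength.  Because around three quarters of
responses are "same", central tendencies of R carry little information;
per-participant extreme values (minimum and maximum) within each state are
the informative statistics, and their cross-participant distributions are
non-Gaussian and asymmetric.  They are therefore compared with the
Brunner–Munzel test, implemented here directly: midranks for ties, the
relative effect p̂ = (R̄₂ − (n₂+1)/2)/n₁, separate rank variances, a
Welch-type estimated df, and two-sided p-values from the t reference
distribution.  Two degenerate regimes are handled explicitly: all values
identical across both samples is an error (no test exists), while complete
separation returns p̂ ∈ {0, 1} with an infinite statistic and p = 0, the
statistic's limit.  NoT means per state are compared with a paired t-test;
participants lacking one state are dropped from the pairing and reported.
A zero-variance, zero-mean difference vector yields t = 0, p = 1 rather
than NaN.

d-standardization subtracts a per-participant reference statistic — their
own minimum, mean, or maximum of the measure — from each raw value,
yielding dMin/dMean/dMax variants of both R and NoT.  Missing values
propagate; nothing is imputed.

## Event-locked interval series

Each usable mind-wandering probe (both subtypes pooled) anchors a segment.
Offsets Δ (hours) from the reference map to half-open one-hour bins by
k = ⌊Δ⌋ with k ∈ {−8…8}: 17 bins, the reference in bin 0, 8 h 59 min after
still in bin 8, 9 h 1 min excluded.  Members must share the reference
probe's calendar probing day — segments never bridge nights.  When mind
wandering recurs within a day, segments overlap and the same probe
legitimately appears in several segments at different lags.

Binning averages within participants first (all of a participant's values
landing in bin k, across their segments), then takes the unweighted grand
average over contributing participants.  Edge bins have fewer contributors
because a ±8-h lag requires a long daily span; no interpolation is ever
applied to missing bins.

The placement check computes each participant's per-bin probability of a
mind-wandering report and tests the 16 non-reference bins with a one-way
repeated-measures ANOVA on complete cases.  Sphericity is untenable here —
bins differ in per-cell precision and shared probes correlate neighbouring
bins — so the Greenhouse–Geisser-corrected p-value is reported (via
pingouin); without the correction the test rejects a uniform null roughly
three times too often, with it the empirical level is 5.0% (500
relabeling replicates of a default cohort).  Exactly zero between-bin
variance short-circuits to F = 0 rather than 0/0.

## Cluster bootstrap and percentile normalization

Probe counts differ across participants and bins, and a participant's
probes are temporally dependent, so uncertainty is quantified by
resampling whole participants with replacement (cluster bootstrap,
B = 2000 by default) and recomputing every bin's grand average per
resample; a resampled participant lacking a bin contributes nothing to it.

Each observed grand average is assigned a midrank percentile,
100·(#below + ½·#ties)/N, within the distribution *pooled across all 17
bins'* resampled grand averages (per measure).  Pooling is what makes the
percentile informative across bins: a bin's own bootstrap cloud is always
centred on its observed value, so scoring each bin only against itself
would park every bin near 50 regardless of signal.  Against the pooled
reference, exchangeable cohorts still average 50 (measured 50.3 ± a few
tenths at B = 2000), while event-locked structure pushes bin 0 into the
tails — the NoT percentile near the top, the R percentile to its minimum.
A consequence worth knowing: within one series, the percentile ordering of
bins equals the ordering of their grand averages.

The trajectory pairs dMean-NoT percentiles (vertical) with dMin-R
percentiles (horizontal) — the pairing using the statistic most sensitive
to state differences — with all nine d-variant pairings available through
configuration.  Points with either axis missing are flagged, not
interpolated.  Inter-individual variability is a leave-one-participant-out
jackknife: each participant is removed, both percentile series are
recomputed (fresh bootstrap, deterministic per-leave-out seeds), and the
radius at each bin is the root-mean-square Euclidean displacement of that
bin's point, in percentile coordinates.  Bins with fewer than three
contributing participants (configurable) get a missing radius.

Period structure in a binned series is read off its missing-data-aware
autocorrelation: the lag of the first positive-lag local maximum, searched
up to lag 8 for the 17-point series.

## The synthetic cohort generator

The generator emulates the probing protocol — 5 probes/day for 14 days
plus one extra on the last day (71 per participant), integer-minute gaps
within [10, 144] min, all probes inside the participant's 12-h window —
over latent per-participant processes:

* λ(t) = max(0, a₀ + a₁·sin(2πt/P + φ) + ε_λ), the thought-generation
  intensity, with P the ultradian period (4–6 h; default 5 h) and φ a
  per-participant uniform phase;
* c(t) = clip(c₀ + g·sin(2πt/P + φ) + drops + ε_c, 0, 1), the control
  level, where drop events arrive as a Poisson process and each subtracts
  `drop_depth` decaying linearly to zero over `drop_recovery_hours`.

Observables: NoT ~ Poisson(λ) truncated at 10 (respecting the dropdown's
integer, non-negative support); the true state is mind wandering iff
λ ≥ λ-threshold and c ≤ c-threshold — control collapsing while the thought
cycle is still up — with the with/without-task label an independent coin;
P(non-same rating) = logistic(intercept + slope·c), non-same magnitude
(little/much) a coin, and direction biased toward "farther"
(`nonsame_farther_prob` = 0.9, a boundary-extension-like reporting bias).
The direction bias is a deliberate modelling choice: with a fair sign the
expected R score would be identically zero at every control level and the
binned R series would carry no event-locked signal at all; the bias gives
mean R the same direction as control strength, at the cost of a mean-level
state difference the extreme-value analysis does not rely on.  Everything
is a pure function of (parameters, master seed); participant streams are
split with `SeedSequence((master_seed, index))`.

Schedule gaps are drawn as a mixture — 85% uniform over [100, 144] min,
15% uniform over [10, 60] min — rather than i.i.d. uniform over the full
range.  Uniform gaps would put the five probes in a ~5-h clump, starving
the ±8-h bins that the event-locked analysis needs; the mixture spreads
most days over 7–9.5 h while keeping adjacent-hour probe pairs (which are
what populates bin −1 under floor binning).  Rejection sampling redraws
any day spilling past the window end.

Default parameters (a₀ = 1.2, a₁ = 0.9, P = 5 h, c₀ = 0.62, g = 0.04,
drops 2.5/day × depth 0.6 × 2-h recovery, thresholds λ ≥ 1.0 and c ≤ 0.66,
rating slope 10 / intercept −7.6, noise SDs 0.3 and 0.22, 8% declines,
0.5%/1% alcohol/display flags) were calibrated once to the marginal rates
the protocol is known to produce — roughly 36% mind-wandering incidence
and 25% non-same ratings — and then frozen.  Ten-seed checks give 34.6%
mind wandering and 26.4% non-same.

`SimParams.with_tied_drops()` is a named variant for validating the
event-locked control signal: mind wandering becomes purely drop-triggered
(λ-gate off), drops are frequent, deep, and fast-recovering (8/day, depth
0.9, 1.25-h recovery, c ≤ 0.35, control noise 0.12), the control/thought
coupling is zeroed so drops are the only event-locked structure, and
non-same ratings are common with a high "much" share so every
participant's R minimum reliably reaches −2.  The last two points matter
for a subtle reason: with dMin standardization, participants whose minimum
never leaves −1 or 0 live on a compressed d-scale, and because the sparse
edge bins sample a participant subset, that heterogeneity masquerades as
an edge-bin signal.  Under this variant the dMin-R percentile minimum
falls in bin 0 in ~93% of cohorts (pooled over 60 seeds).

What the generator does *not* emulate: circadian (24-h) modulation beyond
the hard daily window, day-of-week effects, drifting response styles,
question-order or reactivity effects, and any dependence of rating
behaviour on thought content.  Passing tests therefore show that the
pipeline recovers the structure this model injects at realistic protocol
sizes — not that real cohorts contain that structure.

## Numerical conventions and problem sizes

Bootstrap and jackknife results are bitwise reproducible from (input, B,
seed).  Midrank percentiles avoid 0/100 artifacts under ties.  Bin
assignment uses half-open floors, so boundary probes are never double
counted.  The test suite runs the expensive calibrations at the sizes the
protocol itself fixes — 28-participant cohorts, 71 probes each — with 20
seeds for recovery rates, 500 replicates for test levels, and B = 2000
for percentile checks; unit tests use smaller cohorts and B for speed.

## Known limitations

* The pooled-reference percentile makes bins comparable but means a
  single bin's percentile depends on the other bins' signal; a flat
  series with one extreme bin will push the others slightly off 50.
* The homogeneity ANOVA uses complete cases only (participants covering
  all 16 non-reference bins), typically ~a third of a default cohort;
  its power against localized inhomogeneity is accordingly modest.
* The jackknife radius mixes leave-one-out displacement with bootstrap
  Monte-Carlo noise; at B = 2000 the latter is small but not zero.
* Brunner–Munzel p-values use the t approximation, which is anticonservative
  below roughly 10 observations per group; cohort-level comparisons here
  operate on 20–30 participants per state.
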