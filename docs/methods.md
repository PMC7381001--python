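# Methods

This note documents the analytical rules the package implements, the
defaults it ships, the data-generating process the simulator assumes,
and the places where the design was genuinely open.

## Event model and units

All events are calendar-dated (day resolution); times of day are out of
scope. Age is the static sign-up age. A bleeding day may carry an
intensity in {light, medium, heavy} or be `unreported` — logged as
bleeding but without an intensity. Intensity parsing is
case-insensitive with the synonym map {L→light, M→medium, H→heavy};
any other string becomes `unreported` with a warning rather than an
error, because real tracker logs are messy and a stray string should
not abort an ingest. At most one menstruation record and one LH record
per (user, day) is enforced by validation, which reports issues rather
than raising.

## Cycle segmentation

Cycle boundaries are the logged first days of menstruation. Bleeding
days are first grouped into periods: two logged days belong to the same
period when at most `merge_gap_days` (default 1) unlogged days lie
between them. The 1-day default bridges a single missed log inside a
period; it cannot merge two true periods, which are separated by the
intermenstrual interval (order 20+ days at plausible cycle lengths).
Results should always be reported together with this knob's value.

Cycle length is the date difference between consecutive period starts
(start day included, next start excluded), which makes the per-user
telescoping identity exact: the completed lengths sum to last start
minus first start. The last period opens the current cycle, whose
length is undefined. Completed lengths outside [10, 90] days are
flagged, never silently dropped; `SegmentationConfig.exclude_flagged`
optionally removes them from per-woman statistics (off by default,
since no hard drop rule is part of the analysis definition).

## Inclusion rules

Included: age ≥ 18, no pregnancy logged, no OC reminder, ≥ 2 completed
cycles plus a current one (≥ 3 recorded cycles — the minimum for a
median over completed cycles plus an ongoing one). Excluded users are
attributed to the *first* failing rule in the fixed order age →
pregnancy → OC → cycles; only a final cohort N is conventionally
published, so a deterministic order is our choice to make tallies
reproducible and partition-complete. The pregnancy/OC flags are taken
as given, with no windowing: whether a flag ever set should count is
not derivable from the data model, and the flag-as-given reading is the
simplest consistent one.

## Flow scoring

Scores: light = 1, medium = 2, heavy = 3; unreported days carry no
score. Rules, per cycle:

1. period span ≤ 2 days → light (no mean computed);
2. span ≥ 3 days and fewer than half the days intensity-logged →
   `not_tracked`;
3. otherwise the mean score over logged days classifies the cycle:
   light < 1.5 ≤ medium < 2.4 ≤ heavy. The asymmetric 2.4 heavy
   boundary is kept exactly as published.

Two deliberate readings: the boundary case of exactly 50% logged is
*computed* (the explicit "<50% → not tracked" operational rule wins
over the looser "more than half" phrasing), and the mean is over logged
days only — averaging zeros for unlogged days would conflate
missingness with lightness. The logged fraction's denominator is the
period's day *span*, so unlogged days bridged into a period count
against tracking coverage.

Per woman, the package reports the modal category over her classified
cycles, ties broken toward the heavier category, absent if no cycle is
classifiable. The published per-woman aggregation rule is unstated;
the modal rule is this package's documented choice (alternatives —
latest cycle, mean of means — are easy to compute from `flows.csv`).

## Per-woman statistics

Variance is the population form var(x) = E[(x − μ)²] (divide by *n*),
exactly the printed expectation formula, not the n−1 estimator.
"Variation" is reported in days as sqrt(var): the formula yields days²
while variation bins are stated in days, and the square root is the
only unit-consistent reading; both quantities are retained in output.
The median is the midpoint median (mean of the central pair for even
*n*), rounded half-up where an integer day is needed. Rounding is
half-up throughout (0.5 → 1) — deterministic and matched to integer-day
binning, unlike banker's rounding. Summaries require ≥ 2 completed
cycles; the current cycle never contributes to length statistics (its
length is undefined).

BMI = latest logged weight (kg) / height (m)²; categories use half-open
intervals <18.5, [18.5, 25), [25, 30), [30, 35), [35, 50), ≥ 50, which
close the cosmetic gaps of printed labels like "18.5–24.9". A tiny
epsilon (1e−9) on the comparisons absorbs binary float error so that a
value landing exactly on a boundary classifies as intended. Missing
height or weight yields an absent BMI: the woman stays in the cohort
but not in BMI stratifications. Age groups are the closed integer bins
18–24, 25–29, 30–34, 35–39, 40–55; ages above 55 clamp into the top
group with a warning.

## Ovulation and phases

Cycle days are 1-based. Within a cycle's date window (completed:
[start, next start); current: [start, extraction]) the *last* positive
LH test is used; ovulation is the next day. Follicular length =
ovulation day − 1; luteal length = cycle length − ovulation day + 1,
the ovulation day counting as the first luteal day — this makes a
day-14 ovulation in a 28-day cycle a 15-day luteal phase and the two
phases partition the cycle exactly (an invariant the tests enforce). A
positive test on the cycle's final day would put ovulation outside the
cycle; the estimate is discarded rather than reassigned, keeping at
most one estimate per cycle. Phase distributions are per *cycle* with
explicit denominators (the count of estimated cycles), never per woman.

## Aggregation conventions

Percentages are computed as round-half-up to two decimals (tables) or
one decimal (figure-style histograms); every output row carries its own
numerator, denominator and percentage, and denominators follow the
per-variable "n = ..." convention — missing answers shrink the
denominator, nothing is imputed. Ovulation-day and luteal-length
distributions print fixed spans (11–29 and 5–20 days) with an explicit
`other` bucket for values outside. Re-running on the same log is
bit-identical; there is no randomness downstream of the generator.

## Synthetic cohort generator

Per woman *i*: latent mean m_i ~ Normal(28.5 + group shift, 2.5)
truncated to [15, 60] days; within-woman SD s_i ~ Gamma(shape 4,
scale 0.5) (mean 2 d); completed cycle count uniform on 3–11; observed
lengths round(Normal(m_i, s_i)) clipped to [15, 90] — inside the
segmentation plausibility window, so recovery tests are not confounded
by flagging. Periods are 3–7 days with the intensity ramp (M, H, H, M,
L), truncated or extended to the period length, each day's intensity
logged with probability 0.8. Periods are laid backwards from the
extraction date (2018-12-01) so the last one opens a current cycle.
About 10% of women use LH tests; each of their completed cycles draws a
luteal length round(Normal(14.5, 1.5)) clipped to [5, length − 2] and
logs one positive test the day before the implied ovulation day — by
construction the phase-estimation rule inverts this placement exactly,
which the tests assert cycle by cycle. Flags (pregnancy 5%, OC 5%),
BMI reporting (23%, log-normal BMI with median ≈ 23), and survey
answers (response probability 0.5, category weights patterned on a
young, mostly non-smoking app cohort) complete the profile. All draws
descend from one integer seed through per-user substreams keyed on
(seed, user index), so cohorts are extensible without reshuffling.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: cycle-to-cycle autocorrelation, hormonal or
seasonal trends, age-dependence of cycle length, spotting vs. true
periods, negative or mistimed LH tests (available via `p_negative_lh`
but off by default), inconsistent logging behaviour correlated with
cycle phase, and any real association between surveys and cycle
characteristics unless explicitly planted via the group-shift
parameters.

Two numerical notes on recovery at cohort scale (5,000 users). First,
the per-woman SD estimate from a handful of cycles is biased low (the
population-variance square root at n = 3–11 recovers ≈ 0.87 of the true
s_i), so the cohort mean of `variation_days` sits ≈ 0.2 d below the
generator's E[s_i] = 2; this is a property of the estimator, not a
defect, and stays within the ±0.3 d band the tests assert. Second,
with the population mean at exactly 28.5 d the per-woman rounded
medians split almost symmetrically between 28 and 29; half-integer
medians round up, so the expected modal bin is 29, but its margin over
28 is comparable to sampling noise at this cohort size — the test suite
pins one seed and asserts the expected winner.

## Problem sizes

Unit tests run on 50–400 simulated users; cohort-scale checks use 5,000
users (one shared generation per test session) — large enough for
stable stratified tables and the recovery tolerances above, small
enough to keep the whole suite in seconds. The acceptance script's
smoke run uses 1,000 users.

## Known limitations

- Flow scores are ordinal conveniences; no volumetric interpretation.
- A cycle without a positive LH test is treated as anovulatory for the
  phase tables; the package cannot distinguish "did not test" from
  "tested, never positive" beyond the logged events.
- Conflicting same-day intensity entries are a validation issue, not a
  resolved merge — upstream resolution policy is the caller's.
- The per-woman flow aggregation and the exclusion-attribution order
  are this package's documented conventions, not published rules.
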