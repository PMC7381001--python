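# cyclestats

Menstrual-cycle analytics for period-tracker event logs.

Cycle-tracking apps accumulate day-resolution event streams — logged
menstruation days with a subjective flow intensity (light / medium /
heavy), urinary LH (luteinizing hormone) test results, and sign-up
profile and survey data. `cyclestats` turns such streams into per-woman
cycle characteristics and cohort-level descriptive tables, the way
epidemiological digital-phenotyping studies report them. It is aimed at
reproductive-health researchers who have tidy event exports (or want to
simulate them) rather than access to any proprietary app backend.

## What it computes

For each woman, cycles are segmented from the logged first days of
menstruation: cycle *i* runs from period start *i* to the day before
period start *i+1*, and the last period opens the *current* (incomplete)
cycle. Over her completed cycle lengths *x* the package reports

- mean μ = E[x] and the midpoint median;
- cycle-length variation var(x) = E[(x − μ)²] (population variance, in
  days²) and its square root in days;
- a length category from the rounded median: short (≤ 20 d), normal
  (21–35 d), long (≥ 36 d);
- a flow category per cycle: periods of 1–2 days are light; longer
  periods with at least half their days intensity-logged score
  light = 1, medium = 2, heavy = 3 and classify by the mean score
  (light < 1.5 ≤ medium < 2.4 ≤ heavy), e.g. L,M,H,H,M,L →
  (1+2+3+3+2+1)/6 = 2 → medium;
- ovulation day from LH tests: the last positive test in a cycle marks
  the end of the follicular phase and ovulation is the next day, so the
  follicular phase is `ovulation_day − 1` days and the luteal phase is
  `cycle_length − ovulation_day + 1` days (the ovulation day counts as
  luteal day 1; the two phases partition the cycle exactly).

Cohort-level outputs are stratified count/percentage tables:
demographics, characteristics by short/normal/long median cycle,
per-cycle ovulation-day and luteal-length distributions, and median and
variation histograms by age group and BMI category. Inclusion follows
the usual app-cohort rules: age ≥ 18, no logged pregnancy, no
oral-contraceptive reminders, and at least three recorded cycles (two
completed plus one current).

A seeded synthetic-cohort generator (`cyclestats.simulate`) emulates the
assumed data-generating process — per-woman latent mean cycle length,
between- and within-woman variability, intensity ramps with partial
logging, sparse LH testing — and returns the latent ground truth, so the
whole pipeline is testable without any real data.

## Worked example

```python
import cyclestats as cs

params = cs.default_params("tiny", seed=7)     # 50 simulated users
log, truth = cs.generate_cohort(params)
results = cs.analyze_event_log(log)

print("included:", results.n_included, "of", log.n_users)
print("exclusions:", results.tally.as_dict())
s = results.summaries[sorted(results.included)[0]]
print(s.user_id, s.n_completed, round(s.mean, 2), s.median_length,
      round(s.variation_days, 2), s.length_category)
lut = results.tables.luteal_dist
print(lut[lut["count"] > 0].to_string(index=False))
```

prints

```
included: 44 of 50
exclusions: {'under_age': 0, 'pregnancy': 4, 'oc_reminder': 2, 'too_few_cycles': 0, 'n_included': 44}
u000000 11 27.27 27.0 0.86 normal
 luteal_days  count  denominator  percent
          11      1           41     2.44
          12      3           41     7.32
          13      6           41    14.63
          14      9           41    21.95
          15      6           41    14.63
          16     10           41    24.39
          17      6           41    14.63
```

Six of the fifty simulated users are excluded (four logged a pregnancy,
two had OC reminders). The first included woman has 11 completed cycles
with a 27-day median and 0.86 days of variation — a normal-length,
regular cycle. The luteal table counts *cycles* (41 ovulatory completed
cycles here), each with an explicit denominator, and its mass sits at
13–17 days as the generator's Normal(14.5, 1.5) luteal law implies.

The same pipeline runs from the shell:

```bash
cyclestats simulate --profile tiny --seed 7 --out sim/
cyclestats analyze --config pipeline.yaml   # input paths or a simulate profile
```

`analyze` writes every intermediate artifact (`cycles.csv`,
`exclusions.csv`, `flows.csv`, `summaries.csv`, `phases.csv`, the four
tables and four histogram CSVs) plus a `manifest.json` that suffices to
re-run the analysis identically.

## Layout

- `cyclestats.events` — domain types, three-CSV dialect I/O, validation
- `cyclestats.segmentation` — bleeding-day grouping and cycle building
- `cyclestats.filters` — inclusion rules and exclusion tally
- `cyclestats.flow` — ordinal flow scoring and categories
- `cyclestats.stats` — per-woman statistics, BMI, age groups
- `cyclestats.phases` — LH-based ovulation and phase lengths
- `cyclestats.tables` — stratified cohort tables and histograms
- `cyclestats.simulate` — synthetic cohorts with ground truth
- `cyclestats.pipeline` / `cyclestats.cli` — orchestration and CLI

See `docs/methods.md` for the underlying model, parameter defaults and
known limitations.
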