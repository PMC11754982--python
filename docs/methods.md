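# Methods

## Setting and data model

The analysis concerns an observational cohort of stair-user traversals on
two public stairways (East and West), each with a lower and an upper flight
of 12 steps — 48 steps in all. One stairway at a time carried a
high-contrast striping intervention (a black stripe on each step's top
front edge plus vertical striping on the first and last step faces); the
intervention was counterbalanced between stairways halfway through data
collection, so *condition* (control vs stripe) is an attribute of each
traversal, never inferred from stairway identity.

Two tables drive the pipeline:

- **Step geometry** — one row per step: stairway, flight, step index
  (counted 1..n from the bottom), riser height and tread depth in mm.
- **Observations** — one row per traversal: stairway, flight, condition,
  direction, fall-event flag, optional step index, age group, exclusion
  reason. A *fall-related event* spans anything from a subtle trip or slip
  with minimal recovery through a complete loss of balance.

The raw video data behind the original tables are not public; the packaged
study fixture (below) is a synthetic reconstruction.

## Interstep variation and flight classification

Within one flight, the interstep variation of a dimension is its range,
max − min. A flight is classified **high** variation when its riser-height
range is at least the threshold, else **low**. Defaults and conventions:

- `threshold_mm = 13` (≈ 0.5 in; a convenience converter accepts inches at
  25.4 mm/in). The comparison is inclusive: a range of exactly 13 mm is
  high. The precedent for the half-inch cut is epidemiological: a majority
  of stairway accidents in earlier case series occurred on stairways with
  riser variation ≥ 0.5 in.
- Classification uses the **riser range only**. Tread-depth range is
  computed and reported but does not enter the class: riser and depth
  variation are confounded in this design (the high-riser-variation flights
  are also the high-depth-variation flights), so a two-dimensional rule
  would be unidentifiable here.
- Flight summaries use the sample SD (n − 1 denominator); the source
  reports whole-mm values, so display helpers round half away from zero to
  the nearest mm. A single-step flight has an undefined SD, signalled as
  `None`.
- A step is an **outlier** when its riser height deviates *strictly* more
  than 1 flight SD from the flight mean. With SD 0 no step can deviate, so
  the set is empty.

## Event filtering and cross-tabulation

Traversals are removed when they carry an exclusion reason (assistive
walking devices, not actually traversing, unusual stairway behaviour) or
fall in the under-18 age group; removals are tallied per category and
logged, and malformed CSV rows are collected into a rejects report with row
numbers rather than silently dropped or coerced.

Each retained fall event lands in exactly one of four cells — LC, LS, HC,
HS (low/high variation × control/stripe) — via its flight's variation class
and its own condition flag. The proportions report gives the
high-variation share (hc + hs)/n and, within high variation, the control
and stripe shares; percentages are carried at full precision with integer
display values rounded half away from zero (81.25 → 81, 18.75 → 19).

## The constrained multinomial null test

The study's four directional hypotheses are codified as predicates over
the observed cell counts (lc, ls, hc, hs):

- **A1** hc > lc (strict);
- **A2** |ls − lc| ≤ `a2_max_diff` (default 2, non-strict; `a2_strict`
  selects the "< 2" reading — the two appear interchangeably in informal
  statements of the hypothesis, and the observed data satisfy both);
- **A3** hc ≥ `a3_ratio` · hs (default ratio 2, non-strict; evaluated with
  exact rational arithmetic so integer counts never hit floating-point
  ties);
- **A4** |hc − lc| > |hs − ls| (strict; `a4_absolute=False` selects the
  signed reading (hc − lc) > (hs − ls) — the hypothesis is stated in words
  without signs, and the observed data satisfy both).

The null model allocates the n observed events independently across the
four cells — multinomial(n, p) with n = 20 and p = 0.25 per cell. The
probability that a null allocation satisfies all four predicates is
computed two ways:

1. **Monte Carlo**: 10,000 multinomial draws from a seeded
   `numpy.random.default_rng` generator; `p_hat` is the satisfying
   fraction, with standard error sqrt(p_hat (1 − p_hat) / n_samples).
2. **Exact enumeration**: all compositions of n into four cells —
   C(n + 3, 3) of them, 1,771 for n = 20 — weighted by the multinomial pmf
   (evaluated in log space via `scipy.stats.multinomial`). The enumeration
   also reports each predicate's marginal satisfaction rate and the count
   of satisfying compositions. Above a configurable cap (default n = 500,
   ~21M compositions) the exact route refuses and Monte Carlo should be
   used.

Under the defaults the exact probability is 0.035375 (132 satisfying
compositions), i.e. ≈ 0.04 at two decimals; the Monte Carlo estimate
scatters around it with SE ≈ 0.0018 at 10,000 draws. Because the A2 and A4
wordings admit two readings each, every test report includes the exact
probability under all four codifications (0.0234–0.0722); the defaults
follow the most explicit statement of the hypotheses (non-strict A2,
absolute A4). Observed counts of (2, 2, 13, 3) satisfy all four predicates
under every reading.

Invariants maintained by tests: the pmf sums to 1 over the composition set
(1e−12); relaxing A2 never lowers and tightening A3 never raises the exact
probability; the conjunction probability never exceeds any marginal rate;
Monte Carlo agrees with enumeration within 4 SE across seeds.

## Synthetic data

### Parametric generators

`generate_geometry` draws one flight to per-flight targets (mean, SD,
range for each dimension). Two anchor steps are pinned at mean ± range/2,
so the achieved range equals the spec exactly; the remaining steps are
drawn from a normal truncated to the anchor interval, recentred so the
flight mean is on target (within 1 mm even after clipping), and the values
are randomly assigned to step positions. Only the marginals are published
for the real stairways, so any distribution matching them is admissible; a
truncated normal is the least-structured convenient choice. Infeasible
specs (range 0 with positive SD) are rejected.

`generate_cohort` assigns traversals evenly over flight × condition slots
(matching the balanced, counterbalanced design; an explicit allocation can
be supplied for sensitivity runs) and flips an independent Bernoulli coin
per traversal at its cell's fall rate — traversals are treated as
independent, with no within-user correlation. Event steps are drawn
preferentially from the flight's outlier steps (weight 0.7 by default,
otherwise uniform), because observed events cluster on dimensionally
deviant steps. Direction is ~50/50 ascent/descent and 1.5% of traversals
are over-40, mirroring the cohort's demographics at the level the pipeline
carries them. `calibrate_rates` inverts the expectation: rate =
target count / cell size.

### The study fixture

`study_flights()` and `study_observations()` return a deterministic
reconstruction of the study tables, consistent with every published
marginal:

- 48 integer step measurements whose stairway-level summaries round to the
  published values — risers East 166 (SD 3), West 171 (SD 3), combined
  168 (SD 4) mm; depths East 329 (8), West 327 (8), combined 328 (8) mm —
  with per-flight riser ranges 14/5/14/12 and depth ranges 38/4/38/6 mm
  (lower flights high-variation, upper flights low);
- the four published event-step heights pinned in place: 155 mm (East
  lower, bottom step), 170 mm (East upper, first and last steps), 173 mm
  (West lower, second-to-last step);
- 11,237 observation rows of which the filter removes 100 (assistive
  devices, non-traversals, unusual behaviour, under-18), retaining 11,137
  balanced across stairway × condition (2,785/2,784/2,784/2,784; the exact
  per-cell totals were never published, so an even split is used);
- exactly 20 fall events cross-tabulating to (lc, ls, hc, hs) =
  (2, 2, 13, 3), with the seven step-attributed events on the pinned steps.

The per-event table was never published, so *any* assignment consistent
with these marginals is equally valid; the fixture is one such assignment
and is labelled synthetic throughout. One published statistic is not
reproducible from the published numbers themselves: the claim that 7 of 20
events (35%) occurred on steps more than 1 SD from their flight mean
includes a 173 mm step quoted against mean 171, SD 4 — a deviation of 2 mm,
within 1 SD under either quoted SD (3 or 4). The fixture therefore carries
6 events on >1 SD steps and makes no attempt to force 7/20.

### What passing tests do and do not show

The generators emulate the *statistical* structure the analysis assumes:
balanced allocation, independent rare events, geometry marginals. They do
not model gait, foot clearance, lighting, the visual-illusion mechanism, or
any within-user correlation across repeated traversals. Tests passing on
synthetic data therefore validate the pipeline's arithmetic and contracts,
not the substantive claim that striping causes fewer falls.

## Problem sizes and numerical choices

- Exact enumeration at n = 20 touches 1,771 compositions and runs in
  milliseconds; Monte Carlo at 10,000 draws is vectorised and comparable.
- Parameter-recovery checks run the cohort generator at 100× the study's
  cell sizes (1,113,600 traversals) across 5 seeds, comparing each cell to
  its binomial expectation within 3 SDs.
- All probabilities are compared at tolerances stated per test: 1e−12 for
  pmf normalisation (log-space evaluation keeps this attainable at n = 20),
  4 Monte Carlo SE for the sampling/enumeration agreement (chosen so a
  correct implementation fails with probability < 1e−4 per seed).
- Percent and mm display rounding is half away from zero, matching the
  source's reporting style; all internal arithmetic is full precision.
- Every stochastic entry point takes an explicit integer seed
  (`numpy.random.default_rng`); reports echo the seed and contain no
  timestamps, so a report is a pure function of (inputs, config, seed).

## Limitations

- The fixture is a reconstruction, not the withheld source data; analyses
  sensitive to the unpublished joint distribution (e.g. per-step event
  placement beyond the seven attributed events) are exercised only against
  the marginals.
- The null model treats events as exchangeable across cells with equal
  probability 0.25; it does not condition on per-cell exposure counts
  (which are balanced by design, making the uniform null the natural
  reference).
- The four predicates are parameterised but fixed in form; this is a
  purpose-built test, not a general constraint language.
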