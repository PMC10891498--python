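# Methods

This document states the exact model, parameter conventions and numerical
choices implemented by `dietvalid`, and the limits of what the package
computes. Nothing here is an empirical claim about any real cohort; all
numbers below are either implementation conventions or properties measured
by this package's own test suite.

## Intake model

Grams as consumed for one entry are

```
grams = amount_value × unit_count × unit_factor × edible_fraction? × yield_factor?
```

where `unit_factor` is 1 for grams, the food's density (g/mL) for
milliliters, and the food's per-unit weight for natural units and household
measures (an entry whose unit weight is unknown is *unquantifiable* and
rejected with a diagnostic, not silently zeroed). `edible_fraction` applies
only to units the composition table flags as measured in inedible-including
form. `yield_factor` (per preparation method) applies only when the amount
was reported in the unprepared state.

Fried/deep-fried/stir-fried items with a declared preparation fat absorb
`fat_absorption_fraction × grams` of that fat, which is booked as an extra
amount of the fat food itself (so it lands in the fat's own food group and
nutrient profile). Recipe entries carry a fraction in (0, 1] and are
disaggregated into their ingredient amounts before aggregation. Supplement
entries are excluded from food-group and nutrient totals but tallied as a
recording mode.

Daily nutrient totals are `Σ grams × composition_per_100g / 100`; energy is
the `energy_kcal` nutrient. Daily totals are therefore linear in entries
(additive and homogeneous), which the property tests assert.

## Plausibility screen

BMR is computed from gender, age, weight and height with the Henry
weight-and-height linear equations (MJ/day, converted at 239.006 kcal/MJ).
The coefficients ship as a TSV asset
(`src/dietvalid/data/henry_bmr_coefficients.tsv`) with explicit age bands
partitioning 18–79 years, so they are auditable and swappable. In the
shipped table the women's 60–70 and 70+ rows are identical, as published for
this equation family.

A recording day is plausible iff `0.6 ≤ EI/BMR ≤ 3.0` (closed interval: the
exclusion rule drops days strictly below 0.6 or strictly above 3.0). The
measured physical activity level is PAL = EI/BMR; relative energy
misreporting is `(mean PAL − expected PAL) / expected PAL` with expected
PAL 1.59 by default.

## Statistical conventions

The package authors its own implementations to pin down the exact
conventions; scipy and brute-force enumeration are used as *oracles in the
tests only*.

- **Wilcoxon signed rank** — normal approximation without continuity
  correction. Zeros are dropped before ranking by default
  (`zero_method="wilcox"`); `"pratt"` ranks zeros with the rest and then
  drops them. Ties get average ranks and the variance is reduced by
  `Σ(t³ − t)/48`. Measured against exact enumeration of all 2ⁿ sign
  patterns, the worst-case two-sided p error at n = 8–10 over the test
  suite's random vectors is below **0.1**; this is the documented tolerance
  of the approximation at small n (for n ≥ ~20 the agreement is far
  tighter). All-zero difference vectors return p = 1 with a warning.
- **McNemar** — χ² = (b − c)²/(b + c) on the discordant pair counts,
  referred to χ²₁, no continuity correction by default. When b + c < 10 the
  χ² approximation is unreliable and an exact two-sided binomial test on
  (b, b + c, ½) is used instead. No discordant pairs → p = 1 with a
  warning.
- **Spearman** — Pearson correlation of average ranks (tie-aware); constant
  vectors yield NaN with a warning. Medians of correlation coefficients are
  plain medians.
- **Bland–Altman** — mean difference ± 1.96 × SD with the n − 1
  denominator.
- **Relevance rule** — a method difference is *relevant* iff p < .05 and
  |median_A − median_B| > 0.10 × median_B (strict inequalities, reference
  method B in the denominator). When median_B = 0 the rule is not evaluable
  and the flag is None. Direction (test method lower/higher) is descriptive
  and reported regardless of relevance.
- **Main-table inclusion** — a food group whose 75th percentile of intake is
  0 under both methods is omitted from the main paired table (medians and
  quartiles carry no information there) but kept in the consumer table.
- **Consumer analyses** — a consumer has intake > 0 on the analysis day;
  McNemar compares consumer indicators between methods, and the
  consumers-only Wilcoxon uses pairs who consumed under both methods.
- **SUS** — odd items contribute `response − 1`, even items `5 − response`,
  total × 2.5; any missing item excludes the respondent from the total score
  but not from per-item means.
- **Stratified tables** — per education (3 classes) and BMI class
  (<25 / 25–30 / ≥30); a stratum with fewer than 2 participants is
  suppressed with a warning.

## Matching

Greedy 1:1 matching without replacement, in roster order. The full key is
gender + 5-year age band + 10-kg weight band + education (bands are
lower-inclusive floors). If no unused pool member matches, education is
relaxed first, then age; gender and weight band are never relaxed. Among
eligible candidates the smallest absolute height gap wins, ties broken by
smallest comparator id, making the procedure fully deterministic.

## Synthetic generator

Each food group follows a zero-inflated lognormal: a participant consumes
the group with probability `p_consume`, with consumers-only amounts
lognormal with median `median_g` and log-sd `sigma_log`. The record method
observes `recall × bias × lognormal(0, noise_sigma)` and omits the group
entirely with probability `p_omit`. Per participant, all record-day amounts
are then rescaled by a common factor so that record-day energy equals
PAL × BMR *exactly*, with PAL lognormal (median 1.59) except for a planted
fraction of extreme reporters (`round(fraction × n)`, exact by construction)
whose PAL is drawn uniformly from (0.25, 0.5) (80%) or (3.3, 4.0) (20%) —
outside the screen's closed interval, so the screen recovers them
deterministically. Demographics are allocated by largest remainder to match
the configured proportions exactly at the configured n.

`ground_truth()` returns closed forms where they exist (bias ratio, consumer
probabilities, consumers-only medians — the common per-participant energy
scale factor cancels in within-participant ratios) and computes the
all-participants Spearman correlation by Monte Carlo (default 100 000
simulated participants), since zero inflation, omission and the shared
scaling admit no convenient closed form.

Two shipped configurations:

- `default_config()` — study-condition defaults: cohort mix, per-group
  consumption probabilities/medians and record/recall bias anchored to a
  published consumer table, extreme-reporter fraction 16/227.
- `recovery_config()` — the parameter-recovery configuration used by the
  acceptance suite: six frequently consumed groups with injected bias
  ratios spanning 0.6–1.2, moderate dispersion (`sigma_log` 0.6,
  `noise_sigma` 0.3) and no omission. Rarely consumed groups (consumer
  probabilities near 5%) are *not* identifiable to ±0.05 at n = 1000 — too
  few both-method consumers — so recovery is asserted where the design makes
  the estimand identifiable; this is a property of the sample size, not of
  the estimators.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configs reproduce identical studies and byte-identical output tables, and
  the run manifest records package version, config hash and seed.
- Printed-value comparisons in the acceptance suite treat a value published
  to k decimals as an interval of half-width 5×10⁻⁽ᵏ⁺¹⁾ around the printed
  value, asserted as interval membership (robust to binary floating-point
  representation at the boundary).
- p-value strings such as `<.001` in the shipped summary assets are parsed
  to their bound (0.001), which is decision-identical for any test level at
  or above the bound.

## Scope and limitations

- The generator produces one shared analysis day per participant, no
  intrusions (foods reported by the record but absent from the truth), and
  exercises recipes, household measures, edible fractions and yield factors
  only through the unit-test fixtures, not in generated studies. Recording
  modes are drawn independently of amounts and only affect mode tallies.
- The shipped summary assets are fixed inputs to downstream rules (relevance
  flags, medians of correlations); the package does not — and cannot —
  recompute cohort-level results from raw survey data.
- The pipeline analyses one day per participant pair; multi-day designs
  would need repeated-measures extensions that are out of scope.
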