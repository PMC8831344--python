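# Methods

## Agreement model

The unit of analysis is one nodule measured on two same-day scans, volumes
V₁ and V₂ (mm³). Because the true volume is unknown, the pair mean
V̄ = (V₁ + V₂)/2 stands in for it. Two difference scales are used
throughout: absolute, d = V₁ − V₂ (mm³), and relative,
d% = (V₁ − V₂)/V̄ × 100. Differences are stored signed (scan 1 minus
scan 2, observer 1 minus observer 2); displays may show the magnitude.

For a sample of differences the Bland–Altman summary reports the mean
difference (bias), the sample SD (n−1 denominator), and the 95% limits of
agreement mean ± z·SD with z = 1.96 exactly. The limits are symmetric about
the mean by construction. The confidence interval of the mean difference
uses the t distribution with n−1 degrees of freedom (two-sided 95% by
default): with n = 100, t₀.₉₇₅,₉₉ ≈ 1.984, which is what a published
t-based interval reproduces where a z-interval does not. For n ≥ 4 the CI
is nested inside the limits of agreement; for n = 2 or 3 the t quantile is
large enough that it is not, so the nesting property is only asserted from
n = 4 up.

Nodules are treated as independent even when one participant contributes
several; no mixed-effects adjustment is attempted, and nonparametric limits
are out of scope.

The size sub-analysis stratifies on V̄ (the Bland–Altman x-axis; the choice
of V̄ rather than V₁ or V₂ is a convention decision documented here) with a
default cut of 80 mm³, strata [30, 80) and [80, 150]. The proportional-bias
check converts relative differences to magnitudes and fits OLS of
|d%| on V̄ (statsmodels); the reported p-value is the two-sided test of the
slope. A constant response is returned as slope 0, p = 1 rather than the
0/0 the normal equations would produce.

## Inclusion rules

A nodule is excluded as oversize only when **both** scans exceed the upper
bound, undersize only when both fall below the lower bound (bounds strict, a
volume exactly at a bound is retained), and for poor segmentation regardless
of size. The both-scans rule is what makes retained single-scan excursions
(e.g. 158 mm³ on one scan, 145 on the other) possible, which is why retained
volumes can range slightly beyond the nominal 30–150 mm³ window. No
below-bound single-scan case is distinguished from the above-bound one; the
rule is applied symmetrically. Size is checked before the segmentation flag,
so a nodule that is both oversize and poorly segmented is ledgered as
oversize. Every input nodule ends up exactly once in either the retained
pairs or the exclusion ledger, and the filter is idempotent.

## Growth model

Growth is compounded discretely per surveillance interval:
V(k) = V₀(1+g)^k after k whole intervals, not continuously between visits —
surveillance only observes the nodule at scans. The interval is 3 months,
taken as 92 days for doubling-time conversion: VDT = 92·ln2/ln(1+g) maps
g = 0.15 → 456 days and g = 0.24 → 296 days after rounding (91.25-day
quarters do not reproduce those figures, so 92 is the package default,
configurable via `interval_days`).

Time to the intervention threshold (default 200 mm³) is quantised to the
visit schedule: the earliest scheduled month at which the projected volume
*as reported by the volumetry software* reaches the threshold. "As
reported" means rounded to the software's reporting resolution, 1 mm³ by
default (`GrowthScenario.volume_resolution_mm3`): a projection of
199.9 mm³ reads as 200 and triggers intervention. This matters exactly
once in the default table — 130 mm³ at 24%/quarter projects to
130×1.24² = 199.888 mm³ at month 6 — and the whole-mm³ rule is what makes
the model's intervention windows internally consistent with its own delay
accounting (a 6-month crossing gives the 6-month delay the table reports).
An exact-comparison rule would defer that crossing to month 9.

The management delay is max(0, review month − time to threshold), evaluated
at the fast end of the growth band (the worst case): a nodule presumed
stable because its growth is below the 25% calling threshold waits for the
routine 12-month review even if it crosses the intervention threshold
earlier. Growth classification for a scan pair uses percent change relative
to the **prior** volume, (V_curr − V_prev)/V_prev × 100, strict inequality —
the convention of screening protocols — which is deliberately distinct from
the mean-referenced Bland–Altman relative difference; both conventions
coexist in the package.

Two cells of the published management table this model reproduces are
printing artifacts, verified by exact arithmetic:

- 50 mm³ row, 3-month upper bound: printed 99.2 (duplicating the 80-row
  value); 50 × 1.24 = 62.0.
- 150 mm³ row, 12-month lower bound: printed 262.3; 150 × 1.15⁴ =
  262.3509375, which is 262.4 at 1 dp. The printed value matches rounding
  an already-rounded growth factor (1.749 → 262.35 → 262.3 under float
  display), not full-precision arithmetic.

The golden test freezes those two cells at the exact-arithmetic values and
every other cell at the published value.

Display rounding is 1 dp, half-up ties, applied only at display; because
binary floats sit a hair below decimal ties (115 × 1.15 →
132.2499…97), values are first snapped to 8 dp before the half-up rounding.

## Synthetic cohort generator

The generator emulates the structure of a same-day double-scan study of
small solid nodules:

- **True volumes** uniform on [30, 150] mm³. Real cohorts are right-skewed
  (mean ≈ 81 mm³); uniform is used because under the noise model every
  relative-difference statistic is volume-independent, and the bounds are
  configurable.
- **Measurement noise** multiplicative and size-independent:
  V_measured = V_true(1+ε), ε ~ N(0, σ²) independently per scan. The
  multiplicative form follows from the observed absence of proportional
  bias in relative differences. Gaussian-on-the-linear-scale (rather than
  log-normal) is an assumption chosen for transparency; at σ ≤ 6% the two
  are indistinguishable at test tolerances. The relative difference of a
  pair then has SD ≈ √2·σ, so 95% limits of ±H% calibrate to
  σ = H/(1.96·√2·100); the default σ = 0.056 targets ±15.5%.
- **Second observer**: reproduces observer 1's scan-1 value with
  probability 0.95, otherwise re-measures with fresh noise.
- **Categorical mix**: morphology (spherical smooth / non-spherical smooth /
  non-spherical irregular) at 0.28/0.07/0.65 and location
  (intraparenchymal / juxtapleural / perifissural / juxtavascular) at
  0.80/0.02/0.05/0.13, matching a screening-type case mix. These are
  descriptive only; the noise model does not condition on them.
- **Planted exclusions**: by default 4 oversize (both scans > 150), 1
  undersize (both < 30) and 2 poorly segmented nodules on top of 100
  includable ones, so the inclusion filter retains exactly 100 of 107.
  To keep that accounting exact, an includable nodule's noise pair is
  redrawn in the rare (~1%) event both scans land outside the window on the
  same side; the induced truncation of the noise distribution is far below
  test tolerances at the default σ.
- **Participants**: round-robin assignment (default 45); participant-level
  counts are derived, not stored.

All randomness flows from the single integer seed in `SyntheticConfig`;
identical configs give bit-identical cohorts and byte-identical pipeline
output files.

What passing tests on these cohorts do and do not show: they validate the
statistical machinery (estimator correctness, calibration, invariances) and
the bookkeeping, under an error model that is exactly multiplicative,
Gaussian and size-independent. They cannot validate that real volumetry
error has that form, nor reproduce empirical results that depend on a
specific patient cohort (observed limits of agreement, subgroup values, a
particular regression p-value) — those quantities are covered instead by
consistency checks against published summary moments.

## Problem sizes and numerical choices

Simulation-based tests use 1,000 replicates of n = 100 for calibration
recovery (Monte-Carlo SE of the mean half-width ≈ 0.035%, comfortably
inside the ±0.5% assertion) and single cohorts of n = 10,000 for the
√2-law and categorical-frequency checks (3 Monte-Carlo-SE bands). Small-n
oracle tests compare against direct summation at 10⁻¹² relative tolerance.
Degenerate inputs raise typed errors rather than returning NaNs: fewer than
2 differences, an empty size stratum, a constant regression design, a
non-growing nodule below threshold, non-positive volumes, and probability
vectors off unity by more than 10⁻⁹.

## Known limitations

- Nodule-level independence is assumed everywhere; clustering within
  participants is ignored.
- The generator does not model CT physics (dose, reconstruction kernel,
  slice thickness, inspiration, pulsation); all of it is subsumed into one
  noise term, so sensitivity analyses over acquisition factors are out of
  scope.
- The growth model is deterministic: no growth-rate variability,
  measurement noise at follow-up, or malignancy-risk weighting.
- Published interobserver CIs that are asymmetric about their means cannot
  be reproduced by any standard interval formula and are treated as
  typographical; they are not asserted.
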