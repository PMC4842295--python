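# Methods

## Objective adherence model

### Supply timeline with carry-over

Each eligible therapy is reduced to a per-day availability vector over
the half-open observation window `[T-0, T-0 + 196)`.  The stock
simulation starts 200 days before baseline:

1. on each day, units dispensed that day are added to the stock;
2. if stock ≥ daily dose, the day is *covered* and one dose is
   consumed; otherwise the day is uncovered and stock is unchanged;
3. stock persists indefinitely within the study horizon and stacks
   across refills.

The stock held at the start of the baseline day is the *carry-in*: it
credits patients already on therapy for refills made before the window,
instead of treating the first in-window refill as the start of supply.
Dispensings on the baseline date count as in-window; dispensings after
window end are ignored.  Dropout does not truncate timelines — it only
determines which patients have end-of-study regimen reports and hence
enter the analysis at all.

Two deliberate conventions, since published carry-over rules differ in
detail:

* **Uncovered days do not consume stock.**  A stock-out postpones
  consumption rather than wasting supply; this matches the intuition
  that a patient without tablets takes none.
* **No partial-day credit.**  Stock below one daily dose leaves the day
  uncovered.  All arithmetic is exact — stock is kept as integers scaled
  by the dose denominator — so half-tablet regimens (dose 1/2) incur no
  floating-point drift in day counts.

### MPR and DPPR

MPR is `100 × covered days / window days`.  Because covered days cannot
exceed the window, this form is inherently capped at 100 %.  With
`mpr_cap_enabled = false` the raw supply ratio
`100 × (carry-in + in-window units) / dose / window` is reported
instead, which exceeds 100 % under oversupply; whether the original
study capped is not knowable from its report, so both variants ship
behind the flag, capped by default (it keeps MPR commensurate with the
inherently bounded DPPR).

DPPR is `100 × total covered medication-days / (m × window days)` over
the patient's `m` eligible therapies — identical to averaging the daily
fraction of medications available.  With `m = 1` it equals the capped
MPR.  Both metrics use the strict `< 80 %` non-adherence cut-off; the
cut-off is a config parameter.

### Eligibility rules

A therapy is eligible iff **all** of: daily-fixed regimen; oral form;
definite daily dose; ≥ 1 dispensing strictly before baseline; not
prescribed by a self-dispensing physician; dose not changed during the
window; ATC code not matching the chronic on-demand class prefixes
N02, M01A, N05BA, A12CC (prefix match, so N02BE01 is caught by N02);
form not topical or drops.  Violations are reported exhaustively as
reason codes, not first-hit.

Open point resolved here: "oral forms" includes `oral_other` (oral
liquids etc.) whenever the daily dose is definite, since the dosing
imprecision that motivates excluding creams and drops does not apply to
a counted oral dose.  Pre-baseline redemption is established from the
dispensing ledger itself, not from the reported flag, with "before
baseline" read strictly (the look-back is defined as pre-baseline).

## Synthetic-study generator

The generator emulates the structure of a two-arm pragmatic trial in
~50 community pharmacies: patients on ≥ 4 prescribed chronic medicines,
a 200-day pre-baseline dispensing history, a 196-day window, 2×4
permuted-block allocation per pharmacy, ~17 % dropout uniform over the
window, and near-ceiling self-reported adherence.

**Refill model.**  Each patient carries a ground-truth availability
θ ∈ (0, 1].  A therapy with package size S and dose d alternates covered
runs (one package lasts S/d days; leftovers stack exactly as in the
engine) and stock-out gaps drawn geometrically with mean
`(S/d)(1−θ)/θ`, so the long-run covered fraction is θ by the renewal
reward argument.  The first refill falls in the look-back period at a
uniform phase within one mean cycle, strictly before baseline, which
makes the in-window process approximately stationary — mean engine-measured
DPPR recovers 100θ well within ±2 points at 500 patients (verified in
the acceptance suite at θ = 0.6, 0.875, 1.0).  Package sizes default to
the common 100- and 30-unit long-term packs; the refill-interval mix is
a convention, not an empirical fact.

**Exclusion attributes.**  Per therapy, configurable probabilities of:
on-demand ATC product (default 0.20), non-oral form (0.10), in-window
dose change (0.12), self-dispensing prescriber (0.05).  Defaults chosen
once to yield roughly half of registered therapies eligible, the order
of magnitude seen in practice; parameter-recovery runs set all rates
and dropout to zero, because dropped-out patients have no end-of-study
regimen report and would never enter a real adherence analysis.

**Surveys.**  Each patient holds a latent adherence level drawn from a
normal with mean 96 and SD 8 truncated to [0, 100] (the observed
near-ceiling scale location); observed VAS values add N(0, 4²)
timepoint noise, an additive arm effect at post-baseline timepoints for
the intervention group, and clip to [0, 100].  Note the ceiling: with
the default baseline the truncation pulls the realised mean to ≈ 92 and
attenuates injected arm effects, exactly as a bounded scale does in real
data; generator self-consistency checks therefore inject effects at a
baseline away from the ceiling.  Likert ratings and the MMAS score are
deterministic-plus-noise transforms of the same latent; BMQ items are
drawn independently around typical necessity/concern levels.  These
simulated instruments share one latent dimension — real questionnaire
data have richer correlation structure, so passing tests demonstrate
correct *scoring and classification*, not psychometric realism.

**DRPs.**  Counts are Poisson (default 1.18/patient, intervention arm
only); categories are multinomial at the reference tally proportions of
the adapted GSASA taxonomy (three information-need subdomains instead of
one "insufficient knowledge" cause, plus "More cost-effective therapy
available").

**Determinism.**  Every stage derives its generator from
`StudyConfig.rng_seed` with a distinct stream offset; identical seeds
give byte-identical tables after serialisation.

## Statistics

* Frequencies: Pearson chi-square **without** continuity correction
  (the correction is available behind a flag); degenerate margins raise
  rather than returning NaN.  A two-sided Fisher exact variant is
  provided for 2×2 tables — for sparse change tables the exact and
  asymptotic p-values differ noticeably (e.g. ≈ 0.052 vs ≈ 0.031 on the
  (30, 14)/(20, 24) table), and no claim is made about which a given
  historical analysis used.
* Ordinal scales: two-sided Mann-Whitney-U with midrank ties.
* Change classification: `delta = after − before`; *improved* iff
  `delta > threshold` (default 5), *worsened* iff `delta < −threshold`,
  missing values → *unknown*.  "More than ± 5" is read strictly: a delta
  of exactly ±5 is stable.  Both 2×2 (improved/worsened) and 2×3
  (including stable) arm tables can be produced.
* Sample size (two means, normal approximation):
  `n = ceil(2 (z_{1−α/2} + z_{power})² (σ/Δ)²)` per group; enrolment
  inflates `2n` by `1/(1 − dropout)` and rounds **up to the next
  multiple of 10** — recruitment is planned in round patient counts,
  and this is the only rounding rule consistent with the pair
  (252 per group, 780 enrolled at 35 % dropout).  A t-based iteration
  would give 253+ per group; the z-form is intentional.
* BMQ: subscale sums and their difference; any missing item voids the
  subscale (no pro-rating), because no defensible imputation rule exists
  for "no answer" on a 5-item subscale.
* MMAS is consumed as a precomputed 0–8 score in 0.25 steps (the
  instrument is proprietary; item scoring is out of scope), banded
  8 = high, 6–7.75 = medium, < 6 = low.

## Validation strategy and problem sizes

* **Oracle equivalence**: the engine's DPPR equals an independent
  brute-force per-(medication, day) matrix oracle exactly, on 500
  random multi-therapy histories with windows up to 50 days.
* **Parameter recovery**: mean DPPR within ±2 points of 100θ on
  500-patient cohorts at θ ∈ {0.6, 0.875, 1.0}, fixed seed.
* **Null calibration**: with zero arm effect, the change-table
  chi-square rejects at the nominal 5 % (±3 binomial SE) over 200
  replicate trials of 200 patients per arm.
* Property tests (hypothesis, derandomised): eligibility monotonicity
  and closed-world reasons, supply conservation
  (`covered days × dose ≤ carry-in + in-window units`), monotonicity of
  coverage in dispensings, change-classification antisymmetry, MMAS
  band partition, chi-square against the direct Σ(O−E)²/E formula.

Cohort sizes (500 patients) and replicate counts (200) were chosen so
Monte-Carlo error sits comfortably inside the stated tolerances while a
full suite run stays in seconds.

## Known limitations

* The stock-out refill model is a single-parameter caricature: real
  refill behaviour has weekday/holiday structure, early refills before
  travel, synchronised multi-therapy pickups and pack-size switching,
  none of which are simulated.
* Survey instruments share one latent adherence dimension; no
  item-level psychometrics.
* Therapies started or stopped inside the window are handled only by
  exclusion (the change-flag filter), not by pro-rated sub-interval
  observation.
* No repeated-measures/mixed modelling of the longitudinal endpoints is
  included; trial comparisons are cross-sectional and change-score
  based.
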