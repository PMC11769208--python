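# Methods

This note documents the model implemented by `msdrisk`, the choices made
where the design was genuinely open, and what the test suite does and does
not demonstrate.

## The risk model

A subject's probability of developing a musculoskeletal disorder (MSD) in
body region *j* within a horizon of *T* years is

    p(A) = Q_j(age + T) · Σ_i X_i,    X_i = q_i · a_ij,

a weighted-sum (utility-index) multicriteria model scaled onto an
age-dependent population baseline.

**Weight coefficients.** Each criterion carries an integer weight score
`B_i ≥ 1`; coefficients are `q_i = B_i / ΣB` and satisfy `Σ q_i = 1`
exactly. Cumulative joint moment is scored 2 where other criteria score 1,
because accumulated load dominates a multi-year forecast. Internally the
engine keeps `q_i` as exact rationals; rounding is presentation only, in
three modes:

* `exact` — full precision, `Σq = 1` to machine exactness;
* `display3` — each value half-even rounded to three decimals (the
  displayed set may sum to 0.999 or 1.001; the normalization check reports
  the residual rather than hiding it);
* `table_match` — like `display3`, but the **last occurrence of the
  largest** coefficient is adjusted so the displayed set sums to 1.000.
  This reproduces reference tables that renormalize the display (2/7
  displayed as 0.285, and a tied pair 0.222/0.223); the tie-break is fixed
  to the last occurrence because that is the convention the packaged
  tables follow.

The three modes exist because published tables of this kind are not
internally consistent under any single rounding convention; the engine must
not bake display rounding into arithmetic. Default mode is `exact`;
packaged tables declare the mode that reproduces their printed cells. A few
printed cells in the packaged tables are inconsistent with their own row
likelihoods under every convention (likely misprints); the packaged JSON
keeps the printed values and flags the one clear outlier (the neck
high-readiness likelihood 0.161, versus ~0.9–1.1 for every comparable
entry) in its `notes`.

**Element likelihoods.** `a_ij` is the ratio of the subject's segment mean
to the population grand mean of the underlying metric, assuming a linear
exposure–risk relation: a segment averaging 5 % above the population gets
`a = 1.05`. Three criterion kinds resolve differently:

* *categorical* (sex; physical readiness grouped low 1–6 / medium 7–8 /
  high 9–10): direct level lookup;
* *proportional* (left/right symmetry; lifting with vs without an
  ergonomic belt): the two level likelihoods blend with the subject's
  shares, `a = a₁c₁ + a₂c₂`, `c₁+c₂ = 1`. Side shares come from the
  left/right split of cumulative moment; belt shares from the subject's
  work mix (defaulting to the trial design's 2:1 unbelted:belted split
  when not stated);
* *parametric* (range of motion, peak moment, cumulative moment): the
  subject-to-population ratio computed at fit time, clipped to
  **[0.1, 3.0]** (configurable) so one corrupt trial cannot blow up the
  factor sum.

Two pathways connect the three parametric metrics to the criteria rows and
both are implemented: `independent` (default) treats each as its own
criterion; `composite` first folds the three deviation ratios into the
1:1:2-weighted score `(r + m + 2c)/4` and uses it for every parametric
row. The choice is recorded in results metadata.

**Clipping.** `Q · ΣX` can exceed 1 for unfavourable profiles (the model
itself is unbounded); probabilities are clipped into [0, 1] and flagged.

## Baseline curves and the time shift

Baseline prevalence per region is quadratic in age with `a₂ > 0` — with
aging, declining capacity and accumulated load jointly accelerate onset.
The packaged canonical curves are published coefficients (neck
`6.67e-5 x² + 0.003 x + 0.213`, shoulder `3e-5 x² + 0.0019 x + 0.3`, elbow
`1.767e-4 x² + 0.0047 x + 0.083`), valid over ages **20–75** (the fitted
and plotted range); evaluation outside warns but proceeds, since the model
extrapolates freely. Ages are continuous years.

Prognosis is a *time shift*: the shifted curve satisfies
`Q_T(x) = Q(x + T)`, i.e. a point with `Q = 0.5` at age 40 appears at age
35 on the 5-year prognosis curve. Shifting a quadratic yields a quadratic
(`a₁ ← a₁ + 2a₂T`, `a₀ ← a₀ + a₁T + a₂T²`), so shifts compose additively
and all three curves' positive derivatives make every profile non-decreasing
in horizon.

`fit_baseline` refits curves from study prevalence records by weighted
least squares (weights ∝ study sample size by default, since larger
studies should pull harder). The exact regression behind the canonical
coefficients is under-determined from the study table alone — plausible WLS
on the packaged records does not reproduce them — so refits are diagnostic:
the coefficient deltas against the canonical curve are reported, never
asserted, and a refit never silently replaces the canonical curves.
Study-age SDs are not used in the fit.

## Feature extraction

Per trial: ROM = max − min of the angle series (degrees); peak moment =
max |moment| (N·m); cumulative moment = trapezoidal integral of |moment|
over time (N·m·s). The magnitude is integrated because the quantity is
accumulated load — signed integration would let flexion and extension
cancel. Per-subject values average over that subject's repeated trials
before any ratio is taken; since only ratios enter the model, the absolute
reporting unit (per-trial here) cancels. Features are treated as constant
over the forecast horizon (the technique-stability assumption); no claim is
made that techniques actually remain unchanged — there are simply no data
on their drift.

Trials are consumed pre-segmented (neutral-pose to neutral-pose). A
threshold splitter (angle within 5° of the initial pose for ≥ 0.5 s marks a
boundary) is provided as a convenience for continuous captures; it is a
rough helper, not part of the model.

## Cohort summaries

* Cohort statistics are sample mean and SD (n−1 denominator) of
  per-subject probabilities per region × horizon, plus the min/max and
  mean ± SD of `ΣX`.
* The male/female gap is `(mean_m − mean_f)/mean_f × 100` (female
  denominator; configurable).
* Extreme-scenario bounds take the lowest/highest-risk level of every
  criterion (proportional criteria pushed to a pure 100/0 share; parametric
  criteria at their observed or supplied likelihood extremes). Because the
  factor sum is separable, these bounds coincide with exhaustive
  enumeration over all level combinations, which the tests verify.
* **Dynamic impact** is defined here as
  `100 · range(ΣX | only parametric criteria varied) / range(ΣX | all
  criteria varied)` — the share of profile spread an individual could
  influence through technique. This is one plausible operationalization of
  "impact of dynamic parameters on risk variability"; results always carry
  the definition string in their metadata so numbers computed under
  different definitions are never silently compared. Published headline
  figures of this kind additionally depend on raw study measurements that
  are not packaged, so they are not assertion targets anywhere in the
  suite.

## Synthetic data

The generator emulates the reference study design: 44 subjects
(16 M / 28 F exactly — the split is deterministic, not drawn), age
28 ± 12 y truncated to [18, 70], height 175.11 ± 11.58 cm, weight
75.30 ± 12.58 kg, readiness scores on a triangular distribution peaking at
7, three scenarios (no assist / patient assist / belt) × three trials, neck
on the midline and shoulders/elbows on both sides. Note that truncation
shifts the realized age mean above 28 (to the truncated-normal mean,
≈ 32); the moment-convergence test targets the truncated-normal closed
form, not the nominal mean.

Motion profiles are parametric curves, not biomechanical simulation: angle
is a half-sine excursion from the neutral pose, moment a sine-squared bell
whose peak scales with body weight (0.13 / 0.60 / 0.27 N·m per kg for
neck / shoulder / elbow — order-of-magnitude values for patient lifting).
Only the ratio structure matters downstream, and it is injected explicitly:
male ROM ×1.1, belt moment ×0.9, patient-assist moment ×0.95, readiness
moment multipliers 1.05/1.0/0.95 (low/medium/high), right:left moment
ratio 1.08, multiplicative log-normal trial noise with CV 0.05. No
published effect sizes exist for these; the defaults are order-of-magnitude
choices, fixed once and labeled as such. Randomness uses one independent
stream per subject spawned from the top-level seed, so enlarging a cohort
never reshuffles existing subjects.

**What passing tests show.** Parameter-recovery tests demonstrate that the
pipeline's estimators recover *injected* effects (belt multiplier, male ROM
multiplier) within sampling error, and that an all-neutral cohort
reproduces the shifted baselines exactly. They do not validate the model
against real outcomes: real IMU data carry sensor noise, segmentation
ambiguity, correlated within-subject structure and technique drift that
the generator deliberately omits.

A small committed reference bundle (6 synthetic subjects, 1 trial per
scenario at 5 Hz) provides a hand-checkable fixture; it regenerates
byte-identically from its seed.

## Numerical choices

* Display rounding is half-even (banker's) via decimal arithmetic; weight
  coefficients in exact mode are `fractions.Fraction`.
* Likelihood-share blends validate `c₁+c₂ = 1` to 1e-9; normalization
  tolerance is 1e-12 (exact mode) / 0.0015 (display modes).
* Degenerate inputs: a single-criterion table is legal (`q = 1`); both-zero
  side loads are a degenerate-input error; subjects whose shifted age
  leaves the curve's valid range are evaluated with an `age_out_of_range`
  flag rather than dropped.
* Test problem sizes: recovery tests run 200-subject cohorts at 5 Hz / 2 s
  trials (feature ratios are resolution-independent, so sparse sampling
  loses nothing); moment-convergence pools three 2000-subject cohorts;
  enumeration oracles cover all packaged tables (≤ 7 criteria, ≤ 3 levels).

## Known limitations

* Criterion weights are demonstrative; the framework ships them as data
  (JSON) precisely so refined weights can replace them without code
  changes.
* The baseline curves inherit the heterogeneity of the underlying
  prevalence studies (different countries, instruments and case
  definitions); the quadratic is a smoothing choice, not a mechanistic
  model, and the elbow curve exceeds 1 near the top of its age range
  (clipped, with warning).
* The linear segment-ratio likelihood assumes proportional dose–risk,
  which is untested for these exposures.
* No inverse dynamics, sensor fusion or orientation estimation: joint
  angle/moment series are inputs, produced upstream.
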