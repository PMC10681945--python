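# Methods

This note documents the statistical model, the substitution arithmetic, the
synthetic-data generator, and the numerical and design choices behind
`milksub`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Survey model and variance estimation

The package treats recall microdata as a stratified multistage sample:
every subject carries a calibrated day-1 dietary weight, a design stratum
and a primary sampling unit (PSU) nested in it. When several two-year
survey cycles are pooled, the analysis weight is the per-cycle weight
divided by `n_cycles` (exposed on `SurveyDesign`, default 1; synthetic data
are generated as a single cycle).

All variances use first-order Taylor linearization with the
**with-replacement first-stage approximation** — the standard public-use
treatment, with no finite-population correction. For a statistic with
per-subject score contributions z_i, PSU totals z_hj are formed and

    Var = sum_h n_h/(n_h - 1) * sum_j (z_hj - zbar_h)^2 .

The same machinery drives:

- **weighted means** (score w_i (y_i - yhat)/Σw), which reduce exactly to
  mean ± SD/√n in the equal-weight, independent-PSU limit;
- **regression sandwiches** (XᵀWX)⁻¹ M (XᵀWX)⁻¹, with M the stratified
  between-PSU covariance of the weighted score totals w_i x_i e_i;
- **population ratios** R = Σw s / Σw t (score w_i (s_i - R t_i)/Σw t);
- **paired t tests**, which are by construction identical to a weighted
  mean of the per-subject differences.

A stratum that contributes to a variance with a single PSU raises an error
naming the stratum; nothing is silently collapsed. Inference uses
t distributions on (#PSUs − #strata) degrees of freedom, two-sided
throughout. The pipeline's demographic stage degrades to point estimates
with an SE of NaN on designs too degenerate for any variance (e.g. a
single-subject input) rather than refusing the run.

**Least-squares means.** Covariate-adjusted group means fit one weighted
linear model with age-group cell indicators plus categorical covariate
indicators (sex, ethnicity, income-to-poverty category), then report each
group's predicted margin with covariates averaged over the pooled weighted
sample distribution (observed-margins convention; the margin convention is
genuinely open and this is the choice made here). Empty or collinear
indicator columns are dropped with a logged note — detected by a tiny
diagonal in an unpivoted QR of the weighted design, removing offending
columns from the right.

**Paired tests for the replacement scenario** are design-weighted; an
equal-weight variant is available behind `weighted=False` for sensitivity,
keeping the clustering structure either way. The add-a-serving scenario is
deliberately *not* tested for significance: every subject receives the same
deterministic increment, so independence assumptions fail; instead a 10%
change in the group mean (either direction) is flagged as meaningful.

**Percent changes** for reporting are rounded half-up to a whole percent,
keeping one decimal below 10 in magnitude — the convention of the tables
this layout mirrors. The underlying unrounded percents remain available via
`flag_meaningful_change`.

## Classification

Beverage groups are pure functions of the 4-digit WWEIA category code
(prefix or exact-code rules); no text matching. Groups overlap by design.
"Caloric beverages, excluding milk" is operationalized as every
beverage-range subgroup 70–79 *except* diet beverages (71) and waters
(77, 78), and excluding the milk groups; the including-milk aggregate adds
milk (10), flavored milk (12) and milk substitutes (1404). "Caloric" at the
item level means strictly positive energy — zero is the only non-arbitrary
cut, and it removes diet drinks from replacement no-ops anyway. The whole
map ships as data (editable TOML), so alternative readings of the caloric
aggregate are config edits, not code changes.

Exclusions are applied in fixed precedence — pregnancy/lactation first,
then unreliable recall, then age outside 6–18 — so a subject failing
several rules is tallied once under the first; only the kept set matters
downstream, but the tally always sums to the number excluded.

Meal occasions: lunch = {2, 11} (Lunch, Almuerzo), dinner = {3, 4, 14}
(Dinner, Supper, Cena), covering English- and Spanish-language recall
labels; fully configurable. Unknown occasion codes are treated as non-meal
and logged once per code.

## Milk profile and substitution arithmetic

The engine of both scenarios is the nutrient profile of one cup-equivalent
of fluid **milk, NFS** ("not further specified", a blend over fat levels;
food code 11100000). The shipped per-cup vector (energy 122 kcal, protein
8.07 g, calcium 290.3 mg, vitamin D 2.99 μg, added sugars 0, ...) was
derived by the package authors as the across-age-group average of the
baseline→adjusted differences in published add-a-serving tables, giving
three independent printed cross-checks per nutrient; the acceptance suite
verifies every one to a unit in the last printed digit. `grams_per_cup`
(244 g) is used only to express replacement volume in cups, never in energy
arithmetic. The per-kcal vector is the per-cup vector divided by its
energy, with the energy component set to exactly 1 so that isocaloric
replacement conserves energy identically (the test tolerance of 1e-9 kcal
absorbs only float summation noise).

Scenario 1 adds the per-cup vector to each subject's daily totals.
Scenario 2 selects the replacement set R — by default all nonmilk caloric
beverages at lunch/dinner; `ssb_only` and `milk_substitutes_only` scopes
expose the narrower readings — sums its energy E, and sets
adjusted = baseline − Σ_R nutrients + E × per-kcal. Flavored milk and milk
substitutes are excluded from R under the default scope ("nonmilk" is read
together with the category list; substitutes sit outside the beverage-range
prefixes). Replacement operates on totals, never rewriting the item table;
an audit mode emits the per-item ledger with the milk grams added back.
Replacing an already-replaced day is a no-op (milk is never in R), and
added sugars can only fall since milk NFS carries none.

## Synthetic data generator

The generator emulates the *structure* of pooled recall microdata, not any
particular survey's sampling fractions, oversampling or nonresponse
adjustments:

- **Design**: 15 strata × 2 PSUs (configurable, ≥2 PSUs enforced),
  subjects allocated to strata in balance, lognormal weights (σ = 0.5)
  drawn independently of intake.
- **Demographics**: integer ages uniform on 6–18; male 0.51; ethnicity
  {NH White 0.57, Mexican American 0.14, NH Black 0.14, other Hispanic
  0.065, other 0.085}; income-to-poverty {<1.35: 0.33, 1.35–1.85: 0.11,
  >1.85: 0.56}; activity and weight-status categories with typical shares.
  Pregnancy/lactation (0.43%) and unreliable-recall (20.3%) flags exercise
  the exclusion stage at rates typical of pooled child recall samples.
- **Consumption**: per category, a Bernoulli consumption indicator and a
  gamma amount (shape 2; right-skewed, nonnegative, like intake data)
  whose conditional mean is (per-capita mean)/(consumption probability),
  so the per-capita mean follows the configured linear age trend exactly.
  Probability and amount are independent given age — a documented
  simplification (no zero-inflation correlation). Category means are
  anchored at age 7 to published pooled levels (milk 210 g/d with slope
  −2.64 g/d/y, flavored milk 91.7 with −6.21, soft drinks 123 with +25.3,
  coffee/tea 33.6 with +13.1, ...), energy densities make caloric
  beverages ≈18% of daily energy, and occasion allocations put the
  expected lunch+dinner nonmilk beverage energy near half a milk cup
  (≈0.3–0.6 cup equivalents across ages). A single composite
  "rest of diet" item per subject (gamma, shape 6, age-trended energy)
  supplies realistic totals for contribution denominators.
- **Truth ledger**: every implied quantity — per-category means by age
  group, slopes, energy shares, expected replaced energy and cups — is
  exportable to TOML in closed form for parameter-recovery tests.

Generation is vectorized over subjects with a fixed category order, so a
fixed seed reproduces tables bit-for-bit across runs and platforms
(`numpy` PCG64 stream).

What passing tests on these data do **not** show: robustness to real-world
measurement error (self-report bias), day-to-day intake variation (a
single recall day is modeled, as in the motivating analysis), correlated
consumption across categories, or survey nonresponse structure.

## Problem sizes and calibration checks

The test suite checks the estimators against independent oracles at sizes
chosen to keep the default run fast while leaving sampling error well below
the tolerances: exact rational-arithmetic expansion of the 8-term variance
sum on a 2×2×2 design; a delete-one-PSU jackknife on 50 random small
designs (2–4 strata × 2–3 PSUs, agreement within 15% relative); trend
recovery over 200 replicates of n = 5,000 (estimate within 3 SE ≥95% of
the time, 95% CI coverage required to land in [90%, 99%]); energy
conservation over 1,000 random subjects; ratio-partition additivity to
1e-9. The acceptance script regenerates a 20,000-subject population, which
the full pipeline processes in a few seconds.

## Known limitations

- No usual-intake (measurement-error) modeling; estimates describe
  single-day intake distributions.
- No multiple-testing adjustment; every test is reported at its nominal
  level.
- LS means use one pooled model with group indicators; per-subpopulation
  (domain) fitting would give slightly different SEs in small groups.
- The shipped milk profile is reconstructed from printed table differences
  (rounded to the table's precision), not taken from a nutrient database
  export; users with database access can supply an exact profile via TOML.
- Weight-status and physical-activity categories are consumed as given;
  the package does not compute BMI z-scores or score activity
  questionnaires.
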