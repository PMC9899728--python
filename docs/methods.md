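# Methods

## The score

The revised Healthy Purchase Index (r-HPI) rates the nutritional quality of
a household's monthly food purchases using nothing but the *expenditure
shares* of food groups — no purchased quantities, no food-composition
matching.  A monthly basket is a household's purchases aggregated over 4
consecutive reporting weeks; shares are percentages of the basket's total
food expenditure after removing condiments, water and baby food from the
denominator (those categories are bought infrequently, stored for months,
or marginal in both budget and energy).

The score is a sum of 15 components:

**Diversity subscore (0–5).**  One point per core group — fruits,
vegetables, starches, dairy products, meat/fish/eggs — whose share reaches
a cut-off set at the population 25th percentile of that group's share
(2.77, 3.50, 2.27, 8.19 and 19.73 % respectively in the population the
score was developed on).  The 25th percentile was preferred to the 10th
because it spreads households more evenly across subscore levels; we expose
both the full-precision cut-offs and the one-decimal values printed in the
published scoring table as named presets (`full-precision`,
`table-rounded`), because the two differ at the boundary (a share of 19.7
passes the rounded cut-off but not the exact 19.73).

**Quality subscore (−8 to +12).**  Ten components scored on half-open
intervals of shares (`[a–b[` means a ≤ x < b): fruits & vegetables (0…4),
cheese (−1…1), milk & yoghurt (0…1, with 0.5 below 2 %), eggs & poultry
(0/1), fish (0…2), red meat (0/−1 above 21 %), processed meat (0…−2), fats
(−1…1, combining the total added-fats share with the animal-fats share),
starches (0…2 on the unrefined-starch share *within* the starches group),
and discretionary foods (0…−3).

The total ranges from −8 to +17.  Two subtleties the interval tables imply
but casual readings miss:

* an all-zero-shares input scores +1.5, because "cheese below 4 %" earns
  1 point and "milk & yoghurt below 2 %" earns 0.5 — absence of cheese and
  sweetened dairy is, by the table, a good sign;
* the −8 floor is a *component-wise* bound, not attainable by any real
  basket: a red-meat share above 21 % forces the meat/fish/eggs group share
  above its 19.73 % diversity cut-off (+1), and keeping dairy under its
  cut-off forces the milk share under 2 % (+0.5).  The lowest score a
  self-consistent basket can reach is −6.5; `worked_example_basket("min-score")`
  constructs one.  The score-bounds enumeration in `score_bounds` treats
  components independently, which is how the published −8…17 range is
  defined.

Boundary conventions follow the printed rule table wherever the running
text disagrees (e.g. milk & yoghurt "≥ 9 → 0" rather than "> 9").
Fractional points are kept as exact binary halves, so totals are exact.
Degenerate baskets (zero countable expenditure) raise an error rather than
scoring 0.

## Reference indicators

Four indicators anchor the score's validity assessment.  All are computed
from basket nutrient totals: raw purchased mass × an as-consumed yield
factor × per-100 g nutrient densities, summed over the basket.

* **MAR** (mean adequacy ratio): for each of 23 key nutrients, the intake
  per 2000 kcal of purchases as a percent of its recommended daily intake,
  capped at 100, averaged.  The capping keeps over-consumption of one
  nutrient from masking inadequacy in another.  The reporting-window
  length cancels in the energy standardisation.
* **MER** (mean excess ratio): the same construction for the three
  nutrients to limit — SFA, free sugars, sodium — against their maximum
  recommended values, *not* truncated at 100 (truncation would pile mass
  at 100 and skew the distribution).  The MRVs are 26.7 g SFA (12 % of a
  2000 kcal standard intake at 9 kcal/g), 50 g free sugars (10 % at
  4 kcal/g) and 2633.5 mg sodium (the adult population median intake,
  used in lieu of a formal maximum).
* **NRF9.3** per 100 kcal: summed percent daily values of 9 encourage
  nutrients (capped at 100 each) minus summed percent maxima of the 3
  limit nutrients.  The nutrient lists and daily values ship as a
  config preset (`fulgoni-2009`-style convention) and can be overridden.
* **SED** (solid energy density): kcal per 100 g of solid food, edible
  weight; beverages are excluded because drinks' water content otherwise
  dominates the denominator.

The 23 recommended-intake values and the NRF daily values shipped with the
package are **illustrative adult values** with realistic magnitudes and
units — the authoritative tables are jurisdiction-specific and
user-supplied.  Every test constructs its expectations relative to
whatever reference table is loaded, so none depends on the placeholder
numbers.

## The adaptation pipeline

`rhpi.adaptation` re-implements the procedure that derived the rule set
from data, so it can be re-run on any panel:

1. **Diversity cut-offs** are empirical percentiles of group shares.  The
   quantile estimator is fixed to linear interpolation (Hyndman–Fan
   type 7, the numpy default) because cut-offs differ across estimators
   at the 0.01 % level and reproducibility requires naming one.
2. **Screening**: univariate OLS of MAR and MER on each (sub)group share.
   Shares with skewed or zero-inflated distributions are encoded
   categorically; the auto rule is: quartiles when more than 75 % of
   households purchase the category, purchaser/non-purchaser when at most
   50 % do, and non-purchaser / below-median / above-median otherwise.
   Predictors associated with either outcome at p < 0.20 are retained
   (the either/both choice is a switch, `screen_rule`); retained
   predictors significantly *negative on both* outcomes are flagged as
   pure dilution — spending on a nutrient-empty category mechanically
   shrinks every other share, so such a category (alcohol being the
   canonical case) predicts both indicators downward and is excluded.
   Survivors enter one multivariate model per outcome; p < 0.05 on a
   joint Wald test selects a component.  For a categorical predictor the
   joint test over its dummies is the decision statistic; per-level
   coefficients are reported alongside.
3. **Cut-off definition**: segmented regression of the indicator on each
   selected share.  Breakpoints become cut-offs.  A segment that is steep
   (|slope| at least half the maximum segment slope) *and* populous
   (≥ 30 % of households) is refined with intermediate cut-offs at the
   3rd decile, median and 7th decile of the share distribution; a
   breakpoint opening onto a flat terminal segment is dropped, since
   awarding further points where the indicator no longer responds is
   meaningless.  The steep/populous/flat thresholds are explicit
   configuration, because the original derivation applied these
   judgements narratively.

**Segmented regression** is implemented in-package (no piecewise-regression
library is a dependency): for a fixed breakpoint count, Muggeo's iterative
linearisation — OLS on hinge terms plus indicator terms, breakpoints
updated by the ratio of the two coefficient blocks — with a quantile-grid
multi-start keyed to a seed, followed by a bounded coordinate polish of
the profiled residual sum of squares (the linearisation's stopping rule
otherwise leaves ~1e-2 bias in the breakpoint).  The breakpoint count is
chosen by BIC over 0…k_max with ties to fewer breaks; each candidate
segment must hold at least 10 observations.  Tests cross-check the fitter
against an exhaustive grid-search least-squares oracle.

## Validation battery

`rhpi.validation` mirrors the published design: Spearman correlations of
the score with the four indicators, the per-nutrient excess ratios, and
total energy (the last should be near zero — the score is meant to measure
quality, not quantity); rank-sum contrasts for age bands and for gender
(restricted to single-adult households, where the respondent's
characteristics describe the whole household); age-adjusted linear-model
contrasts with Bonferroni correction for income quartiles and education;
a positive-deviance contrast — households beating the panel medians on all
three of MAR (above), MER and SED (below) versus the rest, strict
inequalities so median ties fall in the "lower" class; and per-decile
score–indicator correlations across four basket characteristics (total
expenditure, alcohol share, mixed-dishes share, animal-to-plant protein
ratio), with tied deciles reported as merged strata.  Rank-sum tests use
the exact null distribution below 50 observations per group and the
normal approximation above.

## The synthetic panel generator

Real scanner-panel purchase data is proprietary; `rhpi.synthetic`
generates panels with the statistical structure the analyses assume, so
every pipeline stage is testable end to end.

Each household draws a latent diet-quality axis z from covariate loadings
(age 0.25, female respondent 0.35, log-income 0.20, education 0.20, unit
residual variance) plus noise.  Subgroup expenditure shares follow a
zero-inflated logistic-normal composition over the 24 countable subgroups:
log-weights are a subgroup mean plus a z-loading (positive for fruits,
vegetables, fish, unrefined starches; negative for discretionary,
processed-meat and animal-fat categories), a shared "fresh food" factor
correlating fruit and vegetable spending, and idiosyncratic noise;
low-prevalence categories (alcohol, fish, dried fruit, sugared cereals…)
are switched off per household by z-dependent purchase probabilities,
which is what exercises the purchaser/non-purchaser encodings downstream.
Monthly expenditure is log-normal with mean 299 € and SD 161 € per four
weeks, split over weeks by a symmetric Dirichlet.

The diet-quality gradient deliberately flows through **two channels**:
the share composition (scale 0.40 on the z-loadings) and, mostly, the
*choice of items within categories* — nine large categories carry two
item variants of contrasting nutritional quality (leafy vs. starchy
vegetables, lean vs. fatty red meat, plain vs. chocolate biscuits, …) and
the log-odds of filling the category with the richer variant is 0.9·z
plus strong idiosyncratic "brand loyalty" noise (SD 2.0).  Households also
carry a log-normal unit-price level (SD 0.30, independent of z),
reflecting premium vs. discount purchasing.  These two features keep the
score–indicator correlations moderate (≈ +0.65 with MAR, −0.50 with MER,
+0.68 with NRF9.3, −0.66 with SED at the default settings) and the
score–energy correlation low (≈ −0.10), i.e. in the regime the validation
design describes, rather than the near-deterministic coupling a
single-item-per-category generator produces.  About 28 % of generated
households beat all three indicator medians simultaneously (the
positive-deviance class).

Item nutrient densities are constructed per subgroup: energy density and
an "adequacy richness" factor q (nutrients per kcal relative to the
reference intakes — 2.6 for leafy vegetables, 0.1 for chocolate snacks)
plus explicit SFA / free-sugar / sodium densities.  Because MAR, MER and
SED are ratios, they respond to the *mix*, not the scale, of the basket.

An optional calibration step (on by default) iteratively rescales subgroup
expenditures so the 25th percentiles of the five core group shares hit the
published cut-off values, preserving household totals; it converges to
within 2 % relative on panels of a few hundred households and raises a
diagnostic error for unreachable targets.

**What passing tests on synthetic panels do and do not show.**  They show
the machinery is correct: scores, indicators, screening decisions,
breakpoint recovery and the validation statistics all behave as designed
under a known generating process.  They do not show that the published
cut-offs are right for any real population — the generator has no real
price structure, no seasonal or promotional dynamics, no household-size
composition effects, and its item catalogue is 37 synthetic items, not a
real product universe.

A note on null constructions: setting the gradient strength to zero does
*not* decouple the score from MAR — the residual correlation (~0.45) is
the mechanical share→nutrient link that the index exists to exploit.  The
true null requires also flattening the composition table
(`flat_composition=True`), which gives every item identical per-kcal
densities; under that construction the measured |rho| is below 0.05.

## Numerical choices

* Money and shares are kept at full float precision; rounding is
  presentation-only.
* Interval membership is exact float comparison against the configured
  bounds; cut-off values are stored as configuration, never re-derived
  silently.
* The score-bounds enumeration evaluates one representative value inside
  every interval of every component through the public scorer (172,800
  quality-branch combinations × 32 diversity patterns).
* Quantiles: numpy linear interpolation throughout (cut-offs, deciles,
  calibration).
* Rank-sum p-values: exact below 50 per group, asymptotic otherwise;
  Bonferroni multiplication is clipped at 1.
* Reported simulation scales — breakpoint recovery at n = 4000 with 100
  replicates, screening calibration at n = 5000 with 500 replicates, the
  end-to-end battery at n = 4375 — were chosen to estimate the relevant
  rates with standard errors well inside the asserted tolerances.

## Known limitations

* The shipped taxonomy carries the canonical 27 subgroups but no real
  item catalogue; mapping a retailer's product list onto it is the user's
  responsibility, as is supplying genuine reference-intake tables.
* The adaptation pipeline emits per-component cut-off proposals; authoring
  composite rules (the two-element fats component) from them remains a
  modelling decision for the analyst.
* Multi-item till lines, promotions and loyalty-card artefacts in real
  purchase exports are taken at face value by the loader.
* The score is a household-basket measure; it says nothing about
  intra-household allocation or out-of-home consumption.
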