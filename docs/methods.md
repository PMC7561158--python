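# Methods

## Problem and estimands

The package estimates, for each small geographic area a of a state, per
year: the number of births from unintended pregnancies, the percentage of
births that were unintended, the incidence of unintended births per 1,000
resident women aged 15–45, and the corresponding three quantities for
*pregnancies* (total pregnancies per year is a seventh output). "Unintended"
follows the standard survey definition — just before conception the woman
wanted the pregnancy later, or not then or at any future time.

Direct area-level survey estimation is impossible (state surveys have a few
thousand respondents spread over the whole state), so the method transfers
survey information onto the complete birth-record file through two fitted
models and aggregates model predictions instead of survey responses.

## Outcome coding

The maternal survey's five response categories map to the binary outcome as

| response (short code) | default coding |
|---|---|
| wanted later (`later`) | unintended (1) |
| not then or ever (`never`) | unintended (1) |
| wanted sooner (`sooner`) | not unintended (0) |
| wanted then (`then`) | not unintended (0) |
| wasn't sure (`unsure`) | not unintended (0) |

Three schemes are supported: `unsure_as_not_unintended` (default, the
literature convention), `unsure_as_unintended`, and `drop_unsure`
(excludes those rows). The statewide unintended share is monotone in how
much of the "unsure" mass is pushed into the numerator — not-unintended ≤
drop ≤ unintended — and `pipeline.coding_sensitivity` re-runs the pipeline
under all three as a sensitivity analysis.

## Imputation

Missing binary covariates are imputed as 0 and missing continuous
covariates as the median observed in the *fitting* table; every feature
gets a companion `_mi` indicator (1 = imputed). The medians are frozen
into the fitted model and re-applied verbatim to the birth-record file:
computing medians on the application file instead would let the
application data leak into the predictor definition and drift as files are
updated. The transform is idempotent (indicators OR-combine), and a
continuous feature with no observed values at all is an error.

## Survey-weighted c-statistic and model selection

The selection metric is the weighted probability that a random positive
outscores a random negative, pair weight w_i·w_j, ties counting ½ —
computed in O(n log n) by a sorted sweep and verified in tests against
brute-force pair enumeration and against scikit-learn's weighted ROC AUC.

Selection uses K = 5 stratified, seeded folds by default (K is a config
value). Each candidate is fit on K−1 folds with observation weights in its
loss (exact `sample_weight` for all families except the multilayer
perceptron, which scikit-learn does not support weights for; that family
is fit on a seeded weight-proportional bootstrap instead, and the
standardization step is weight-aware so duplicating a row and doubling its
weight are exactly equivalent for the exact-weight families). The winner —
highest mean held-out weighted c-statistic — is refit on all rows; ties
break by the documented family order (logistic, random forest, gradient
boosting, neural net, linear SGD) and then by grid position, so selection
is fully reproducible. The default grid keeps one or two fixed
hyperparameter settings per family; there is deliberately no wider search.

Tree-family winners expose Gini importances, folded over the `_mi`
indicators into their parent covariates and normalized to shares summing
to one. Predictive margins (partial dependence) force one covariate to a
level for *every* row, re-predict, and summarize the row-level prediction
distribution — mean, quartiles, and adjacent values at p25 − 1.5·IQR /
p75 + 1.5·IQR clipped to the observed extremes, all on the percent scale.

## Births → pregnancies extrapolation

With ĝ(Z, y) the fitted live-birth probability, each observed birth is an
inverse-probability representative of the pregnancies behind it:

    Û = ŷ / ĝ(Z, 1),    P̂ = ŷ / ĝ(Z, 1) + (1 − ŷ) / ĝ(Z, 0).

ĝ is floored at `g_floor` (default 0.05) before division: inverse weights
explode as ĝ → 0, and a floor bounds any single birth's contribution at
1/g_floor = 20 pregnancies. The floor is recorded in the config and run
log. In the ĝ ≡ 1 limit the pregnancy table collapses exactly onto the
birth table (Û = ŷ, P̂ = 1). The aggregate unintended-pregnancy percentage
is 100·ΣÛ/ΣP̂; it exceeds the birth percentage whenever ĝ(·,1) ≤ ĝ(·,0)
everywhere, i.e. whenever the fitted model agrees that unintended
pregnancies are less likely to reach a live birth.

## Geography and aggregation

Births are assigned to areas by point-in-polygon on planar mile
coordinates; points on shared boundaries resolve to the lexicographically
smallest area id (a deterministic tie-break for exact tilings), and points
in no polygon are logged as unassigned. Records with missing coordinates
are excluded up front and counted — exclusion accounting (coordinates,
unassigned, undefined incidence) is part of every report.

Per-year counts divide by `years_span` (default 3, the span of the birth
window). Incidence denominators come from the population table as-is.
Default age bins are 15–17, 18–20, 21–24, 25–29, 30–34, 35–45 (closed,
configurable); every area also gets an "all"-ages row and the table ends
with statewide rows. Cells with births but zero resident women get NaN
incidence and are counted, not dropped.

## Density surfaces

The search radius follows the mean-area-per-event rule r = sqrt(2·A/E)
with E the *annual* expected event count — annual counts reproduce both
reference radii for a 69,707 sq mi region (2.4 mi at 24,500 births/yr,
1.9 mi at 40,000 pregnancies/yr), so annual is the default convention.
The kernel is the quartic (biweight), K(d) = 3/(πr²)(1 − (d/r)²)² for
d < r, truncated at r — the kernel used by the GIS tooling such maps are
conventionally made with; the kernel family is a compatibility choice, not
a statistical claim. Events are weighted by ŷ (births) or Û (pregnancies)
rather than thresholded, preserving totals; the surface divides by
`years_span` to read as events per square mile per year. Default cell size
is r/20, at which the discrete surface conserves mass within 1%. Inputs
are planar miles; geographic coordinates must be projected beforehand.

## Synthetic data generator

The generator emulates the study's data environment so that every stage is
testable against known truth:

- **Geometry**: the bounding box is 300 × 232.36 miles = 69,707 sq mi; it
  is tiled exactly by `area_count` rectangles with seeded random
  proportions (default 10 areas; the method's real use case has ~47).
- **Birth records** (default 1,000 per area over a 3-year window): ~20
  covariates with documented marginals (`schema.COVARIATE_MARGINALS`;
  e.g. 41% married, mean age 27.5, ~3% twin births). The latent
  intendedness is logistic in the ground-truth coefficients — dominant
  terms on marriage, insurance, age, parity and prenatal-care month — with
  the intercept *calibrated* so the marginal unintended share equals the
  stated baseline (default 0.34) exactly in expectation. Coordinates are
  uniform within the assigned area; area birth counts follow a lognormal
  urban/rural skew; per-area covariate composition (marriage/insurance
  rates, age shift) varies on a logit scale so area-level heterogeneity is
  *expressed in covariates* and therefore recoverable by a model that
  never sees area ids. Item missingness is injected per-feature; a
  `coordinates` rate (default 0.06%) drops both coordinates jointly.
- **Maternal survey**: a Bernoulli subsample of births (default 5%). The
  five-category response is drawn from fixed conditional splits given the
  latent truth (unintended → later 70% / never 30%; otherwise sooner 25% /
  then 60% / unsure 15% — the splits are artifact choices; only the binary
  coding matters downstream). Weights are gamma perturbations around
  1/sampling_rate — a stand-in that exercises the weighted estimators, not
  a reconstruction of any real survey's weighting.
- **Pregnancy histories** (default 8,000 women, 1 + Poisson(1.2)
  pregnancies each): intendedness from the same family of models
  (calibrated to a 40% unintended share among pregnancies), live birth
  logistic with a negative intendedness term, calibrated to the 0.71
  marginal live-birth share.
- **Population table**: integer women counts per area × age bin, totals in
  the 15,000–36,000 range by default.

Everything is drawn from per-stage child streams of one seed, so a bundle
is byte-identical under a fixed seed.

**What passing tests do and do not show.** The generator's covariates are
(conditionally) independent, its true models are logistic, weights are
noisy but unbiased, and survey response is complete — so parameter-recovery
results demonstrate the pipeline's correctness, not robustness to recall
bias, informative nonresponse, abortion underreporting, regionally varying
associations, or design-based weight structure, none of which it attempts
to emulate.

## Numerical and design choices

- Intercept calibration solves mean(expit(α + lp)) = target by Brent's
  method on [−40, 40]; a target share of exactly 1 short-circuits to
  probability 1 (allowed for degenerate test scenarios).
- The run directory is named by the config hash (output location excluded
  from the hash), so identical configs rerun byte-identically into the
  same place; every CSV artifact embeds the hash, seed and canonical
  config as `#` header lines, and a MANIFEST lists SHA-256 hashes.
- CV c-statistics are reported to two decimals in the run log; full
  precision is kept in the CV table.
- Problem sizes in the test suite (50,000 births with a ~4,000-respondent
  survey for recovery checks, matching the magnitude of the real survey
  samples; 20 two-area replicates for rank recovery) are desk-scale
  choices that keep the suite quick while leaving the binomial standard
  errors well inside the asserted tolerances.

## Known limitations

No confidence intervals are produced (predictions from CV-selected
machine-learning models lack an agreed interval construction, and the
aggregation compounds two models). Associations are held constant across
the state — area variation comes only from covariate composition. Births
to residents delivering outside the region (and vice versa) are out of
scope, as are estimates below the area level. The live-birth model is fit
on a nationally-representative-style sample in the real design; its
transportability to one state is an assumption the package cannot test.
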