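# Methods

`gridsdm` implements a consensus species-distribution-modelling (SDM)
framework for atlas data: species occurrence recorded as presence/absence
per grid cell of a national mapping grid, together with per-cell
environmental predictors.  The framework covers explicit predictor
selection, four niche-model engines, repetition-based validation, strict
majority-vote consensus mapping, fuzzy grouping of species by their
environmental responses, and projection onto climate-shift scenarios with
range-change and extrapolation accounting.  This note records the models,
the defaults, and the design decisions taken where the procedure was
genuinely open.

## Data model

A `PredictorTable` holds one row per grid cell and one column per
environmental predictor, each predictor typed as continuous, ordinal
(e.g. Strahler stream order, 1–9) or categorical (e.g. dominant river type,
ten substrate-oriented classes) and assigned to one of four thematic
categories: climate, topography, hydromorphology, anthropogenic.  Cells
with missing predictor values are dropped on load rather than imputed,
mirroring the usual exclusion of incompletely mapped coastal cells.  An
`OccurrenceTable` carries binary presence indicators per species on the
same cells.  Species with 50 or fewer presence cells are excluded before
modelling (`filter_species`, strict `> 50`): below that, the 70/30
splitting leaves too few validation presences for stable thresholds.

## Synthetic grid and virtual species

The generator produces the study conditions for all tests: a lattice of
2,935 cells (the size of the German TK25 atlas after coastal exclusions)
with spatially smooth fields built as a low-order north–south trend plus
Gaussian-filtered white noise.  Field means and ranges are calibrated to
the published 20th-century baseline for that grid: annual mean temperature
8.4 °C (≈2.5–10.4), isothermality 3.1, temperature seasonality 63.7 °C²,
annual precipitation 732.1 mm, maximum warm-month temperature 22.7 °C,
precipitation seasonality 20.7.  Altitude is lognormal-like with a
mountainous southern tail; temperature is coupled to altitude with |r|
held below the 0.75 collinearity cap for the designated "core" predictors,
while deliberately redundant pairs (warm-month maximum vs. annual mean
temperature, diurnal range vs. isothermality, r > 0.75) give the
correlation filter realistic work.  Strahler order is a discretized
monotone transform of log cumulative upstream length plus noise; river
type and dominant land use are drawn from altitude/substrate-dependent
multinomial utilities.  The smoothing length (default 5 cells) is a free
generator parameter, not an estimate of any real landscape; on very small
lattices it should be reduced (the tests use 1.5–5), because a long
correlation length leaves few independent spatial patches and makes all
smooth fields mutually predictive.

Virtual species occupy the grid with probability exactly
`logistic(intercept + Σ linear + Σ quadratic + Σ categorical offsets)`
(`NicheSpec`); the simulator returns both the Bernoulli draws and the
truth probabilities, so every downstream stage can be checked against a
known oracle.  The default library has six species in three guilds — two
cold-adapted (Gaussian thermal niches with optima 6.0/6.4 °C, below the
landscape mean), two warm-adapted (monotone increasing thermal responses),
and two climate-neutral (driven by Strahler order and river type, which no
scenario shifts).  Niche strengths were set so prevalence falls in the
0.2–0.5 range typical of common atlas species and the Bayes AUC of each
truth map is ≈0.85–0.93, i.e. validation discrimination in the
good-to-excellent band that the projection gate requires.  What passing
tests on these species do **not** show: robustness to rare species, to
dispersal limitation, to spatially autocorrelated detection error, or to
niches that violate the additive logistic form.

Climate scenarios are affine per-predictor shifts
(`value' = value·scale + delta`).  The shipped library has three
mid-century (2050s, A1b) scenarios whose deltas are published
future-minus-baseline means for the same grid: annual mean temperature
+2.4/+2.7/+2.7 °C (ECHAM5/HadCM3/IPSL-CM4), precipitation −15.8/−16.8/
−18.7 mm, with the corresponding isothermality, seasonality, and
warm-month shifts.  Emulating GCM fields as uniform shifts ignores spatial
heterogeneity of change — adequate for exercising the projection
machinery, not for real impact assessment.

## Predictor selection

Selection proceeds in three moves.

1. **PCA representatives.**  Within a thematic group of continuous
   predictors, columns are standardized and the predictor most correlated
   with each leading principal component is reported together with the
   explained-variance fractions.
2. **Correlation cap.**  Greedy elimination until every retained pair has
   |association| < 0.75.  Mixed types use the standard analogues: Pearson
   r between numeric predictors, the correlation ratio (η) between a
   categorical and a numeric predictor, Cramér's V between categoricals.
   The strongest violating pair is resolved first by dropping its
   lower-ranked member (rank = mean univariate ROC; ties keep the
   alphabetically first name).  Greedy rather than optimal search matches
   the iterative character of the procedure; the exhaustive-subset oracle
   in the tests confirms they agree on small instances.
3. **Three-criteria relevance rule.**  A predictor is relevant if at least
   two of: mean univariate ROC ≥ 0.65; mean permutation importance ≥ 5%;
   retained by the models of at least half the species ("at least half"
   read conservatively as ≥ ⌈n/2⌉).  The univariate ROC is the midrank
   Mann–Whitney AUC folded to `max(AUC, 1−AUC)` so descending responses
   score symmetrically; for a categorical predictor the score is its
   per-level presence rate.

In the pipeline the models are offered the correlation-filtered candidate
set and pruned per model by stepwise selection; the relevance report is
then computed from those fits.  A second fitting round restricted to the
relevant set would not change per-model parsimony and is not performed.
The species-retention count treats a predictor as retained by a species
when it appears in at least half of that species' fitted models across
engines and repetitions.

## Engines

All four engines share one contract: fit on calibration cells, predict
scores in [0, 1] on any aligned table as a pure function of (model,
table), and record the calibration min/max of every predictor they use.

**GLM** — binomial logit-linear model (statsmodels), categorical
predictors one-hot against a reference level.  Model search is
bidirectional stepwise AIC from the intercept-only start over whole-term
blocks.  Complete separation (detected by the log-likelihood reaching
numerical zero, where the MLE does not exist) falls back to a
ridge-penalized fit (penalty 1e-4 on the standardized scale) and is
flagged in the model blob.

**GAM** — the same additive structure with each continuous predictor
expanded in a cubic spline with exactly four degrees of freedom and no
smoothness optimisation.  The basis is the truncated-power set
`[z, z², z³, (z−k)³₊]` on calibration-standardized values with one
interior knot at the calibration median: four columns per smooth term,
well-conditioned, and — unlike a B-spline basis clipped to the data hull —
defined everywhere, which matters because scenario projection evaluates
terms beyond the calibration range (the mismatch report quantifies how
often).  Cubic extrapolation beyond the hull is aggressive; that is a
property of unpenalized splines generally and one reason the extrapolation
audit exists.  A continuous predictor with fewer than eight distinct
values is demoted to a linear term with a warning.

**RF** — a bagged classification-tree ensemble (scikit-learn
RandomForestClassifier), 500 fully grown trees by default, one bootstrap
per tree; the reported probability is the fraction of trees voting
presence (with fully grown trees the averaged per-tree class frequencies
equal the vote share).  AIC is undefined for bagged trees, so parsimony
is enforced by forward selection on out-of-bag misclassification with a
one-standard-error stop: a candidate enters only if it lowers the OOB
error by more than one binomial standard error.  Screening fits use a
reduced ensemble (50 trees, minimum leaf 5) purely to rank candidates; the
final model is the full ensemble.  Everything is deterministic given the
seed.

**ME (maximum entropy)** — a Gibbs distribution over the background (all
calibration cells) fitted from presence cells only.  Features are
calibration-standardized linear and quadratic terms of continuous
predictors, linear terms of ordinals, and level indicators for
categoricals.  Weights maximize the presence log-likelihood under an L1
penalty `reg·‖λ‖₁` (default reg = 1), solved by L-BFGS-B on the split
positive/negative parametrization; at the optimum every fitted feature
expectation matches the presence-sample mean to within `reg/n_presences`
(checked as a KKT residual in the tests).  Cell weights are rescaled by
their maximum so the most suitable cell scores 1, making the common
thresholding scheme applicable to all four engines.  The feature classes
and penalty are declared defaults of this implementation, not estimates.

## Validation, thresholding, importance

Cells are split uniformly at random into 70% calibration / 30% validation,
ten times per species; all engines share the splits.  The decision
threshold maximizes min(sensitivity, specificity) over the unique
predicted values on the **calibration** predictions (never the validation
set), with ties broken by minimal |sens − spec| and then by the smallest
threshold — this drives sensitivity and specificity towards equality.
Discrimination is the midrank AUC; bands are fail/poor/fair/good/excellent
on [0.5,0.6), [0.6,0.7), [0.7,0.8), [0.8,0.9), [0.9,1], with below-chance
scores reported as "fail".

Permutation importance of predictor v is `max(0, 1 − r̄_v)`, where `r̄_v`
is the mean Pearson correlation between intact-table predictions and
predictions after permuting column v (20 permutations by default; 10 in
the pipeline, on a 1,000-cell calibration subsample — at that size the
correlation is estimated to ±0.03, and the saving matters for the
500-tree forests).  Raw importances are normalized to percentages summing
to 100 per model; predictors not in the model get exactly 0 (permuting an
unused column cannot change predictions).  Pearson rather than rank
correlation is used; for monotone prediction changes the two are close,
and Pearson makes the equal-coefficient 50/50 check exact in expectation.

## Consensus and response clustering

Binary member maps (engine × repetition, and × scenario for projections)
are merged by strict majority: a cell is presence only if **more than**
50% of members vote presence, so an exact tie in an even ensemble is
absence.  Consensus is over binarized members, not averaged probabilities
— thresholds are engine-specific, so probability averaging would mix
scales.  The default current-condition ensemble is GLM+GAM+RF × 10
repetitions = 30 members; ME is fitted and evaluated but excluded from
consensus by default because its suitability scale depends on occurrence
frequency.  Map agreement is the coincidence rate: the fraction of cells
two maps assign identically.

Each species' mean importance profile is collapsed to three shares —
climate (C), altitude (H), hydromorphology (HY) — by summing PI within
groups and dividing by the total (anthropogenic predictors carry no group
and are excluded from the shares).  Species are clustered on the 3-share
simplex by fuzzy c-means with c = 4, fuzzifier m = 2, Euclidean distance
(the standard Bezdek defaults), 20 random restarts, best objective kept,
deterministic given the seed.  Cluster labels are arbitrary, so reports
renumber clusters by descending mean altitude share, and recovery tests
compare partitions under the best label matching.  Clustering runs
separately per engine.  Clustering on the 3 shares (rather than the full
per-predictor PI vector) is the default; the full-vector mode is available
by passing the PI matrix directly to `fuzzy_cmeans`.

## Projection and uncertainty

Only species whose mean validation ROC over the consensus engines reaches
0.8 ("good") are projected.  Every (model, scenario) pair is binarized at
the model's stored threshold; per-scenario consensus and a joint consensus
over all pairs (3 engines × 10 repetitions × 3 scenarios = 90 members)
follow the same strict majority rule.  Loss (gain) is the percentage of
currently occupied cells predicted vacated (newly occupied), both relative
to the current occupied count, so gain can exceed 100%.  The change table
reports three marginals: per engine (that engine's repetitions across all
scenarios), per scenario (all engines), and "Mean" (joint vs. current).

The extrapolation audit takes, per predictor used by a species' ensemble,
the union of calibration ranges across repetitions (min of mins, max of
maxes — the least conservative choice consistent with one range per
species and predictor; per-repetition ranges would only enlarge the
mismatch) and reports the percentage of cells whose projected value falls
outside it, plus the union percentage over all used predictors ("total",
necessarily ≥ every per-predictor value).  Whether real-data analyses of
this kind compute ranges on calibration splits or all cells is usually
unstated; calibration splits are used here since extrapolation is defined
relative to what the model saw.

## Determinism and problem sizes

All randomness flows from one master seed: stage seeds and per-model seeds
are CRC32 hashes of `(master, stage/engine, species, repetition)` reduced
below 2³¹, recorded in the run manifest.  The default study size — 2,935
cells, 6 species, 4 engines, 10 repetitions, 3 scenarios — runs in
minutes on one core; unit tests use 300–3,000-cell grids, which is enough
for the parameter-recovery and oracle checks because those are exact or
have binomial error bounds that the tests state explicitly.

## Known limitations

- No dispersal constraints, biotic interactions, or barrier effects; like
  all correlative SDMs, the framework assumes niche stability and
  equilibrium with the environment.
- Uniform scenario shifts cannot create novel spatial patterns of change.
- The ME engine's features and penalty are fixed defaults; no
  cross-validation of `reg` is performed.
- The RF serialization stores seed and hyperparameters for regrowth rather
  than the trees themselves; regrowing requires the original calibration
  data.
- Stepwise AIC is order-dependent in principle; with the small candidate
  sets used here the bidirectional search with strict improvement is
  stable in practice, but it is not guaranteed to find the global AIC
  optimum.
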