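# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Notation: DNAm levels are
percent methylation in [0, 100]; ages are in years; `R` is the Spearman rank
correlation between methylation and age at one CpG.

## The analysis protocol

The pipeline operates on a cohort with two populations — a large *pool*
(German-like) and a smaller fixed *reference* (Japanese-like) — over a
22-CpG panel in *PDE4C*, *ELOVL2*, *RPA2*, *EDARADD* and *DDO*. In order:

1. **Age restriction.** Donors outside the closed interval [10, 65] years
   are dropped. The interval is closed at both ends; the source protocol
   says "between 10 and 65" without a boundary convention, and inclusivity
   is the documented choice here.
2. **Correlation screening.** Per CpG, Spearman R between methylation and
   age is computed over the cohort supplied by the caller; sites with
   |R| < 0.75 are excluded. The absolute value is deliberate: the two
   *EDARADD* sites correlate strongly *negatively* with age and are
   age-informative, so a signed reading of the rule would be inconsistent
   with keeping them while dropping *DDO* (R ≈ −0.73). The screening cohort
   is an explicit argument because the reported correlations are ambiguous
   about whether they were computed before or after the age filter; this
   package calibrates and screens inside the [10, 65] window.
3. **Population-difference testing** (`run_popdiff`). The reference group is
   tested against 500 (configurable) age- and sex-matched subsamples of the
   pool. Per run and CpG an ANCOVA — `y = b0 + b1·age + b2·group`, F test of
   the group term against the age-only model on F(1, n−3) — yields a
   p-value; per CpG, the runs are summarised by the median p and the
   percentage of runs with p < α (α = 0.05). Sex is controlled by matching,
   not modelled as a covariate, and no age×group interaction is fitted
   (slope homogeneity is assumed; an interaction mode and a permutation
   p-value exist for robustness checks but are off by default).
4. **Evidence classification** (`classify_sites`). *strong*: median p < 0.05
   and > 75 % of runs significant; *suggestive*: median p < 0.05 and > 50 %;
   *none*: median p > 0.3; otherwise *intermediate*. The 75/50 cut-offs are
   qualitative conventions (config-exposed), chosen to mirror the way the
   original table highlights its rows.
5. **Prediction-impact evaluation** (`run_eval`). Per run, a matched test
   subsample of the pool is held out, a fresh forest is trained on the
   remaining pool donors (strict train/test separation, one model per run),
   and MAE and mean age gap (estimated − chronological) are recorded for the
   held-out subsample and for the fixed reference group. Means and medians
   over runs summarise each group; medians of even run counts use the
   arithmetic midpoint.

### Matching

A matched draw reproduces the reference group's size with all balance tests
above a threshold (default p > 0.3). The balance tests are not prescribed by
the source protocol; the conventional reading implemented here is a Welch
two-sample t test on age and a chi-square test (Fisher's exact below
expected counts of 5) on the 2×2 sex table. The default *stratified*
strategy matches sex counts exactly — trivially available because the pool
outnumbers the reference in both sexes — and rejection-samples ages within
sex, so p_sex = 1 by construction and only age balance is stochastic. Whole
candidate subsets are resampled rather than optimised donor-by-donor
(no propensity scores, calipers or nearest-neighbour pairing), keeping
accepted draws exchangeable subsamples of the pool. Failure to accept
within `max_attempts` (default 10,000) raises an error carrying the best
attempt's p-values; there is no silent fallback. A Kolmogorov–Smirnov age
test is available as an option.

### Dependence caused by the fixed reference group

The reference group is *the same* in all runs, exactly as in the source
protocol. Consequently run-level p-values at one CpG are strongly dependent:
the reference group's realised noise mean (standard deviation
≈ σ·√(1/83 + 1/287) ≈ 0.125 σ against a per-run subsample component of
≈ 0.093 σ) acts as a persistent pseudo-effect present in every run. The
*marginal* distribution of a run p-value under the null is uniform (the
package verifies this over fresh cohorts), but *conditional* per-CpG
aggregates scatter widely: a CpG whose reference draw happens to sit near
the pool mean yields far fewer than 5 % significant runs, while an unlucky
draw (|z| ≈ 2) yields 20–40 %. Percent-significant values per CpG spanning
0–40 % under the null are therefore expected behaviour of the protocol, not
a defect — the published results table shows the same signature (sites with
0.68 % and 0.94 % of runs significant). Interpreting per-CpG aggregates
should always account for this shared-reference dependence.

## The curvature-test random forest

The age regressor is a bootstrap aggregate of regression trees
(`CurvatureForestRegressor`, an sklearn-compatible estimator):

- **Bootstrap.** Each tree trains on a with-replacement resample of the full
  training set (resample size = training size); 10,000 trees in the
  reference configuration. Out-of-bag bookkeeping is optional
  (`compute_oob`).
- **Split-predictor selection (curvature test).** At a node, every candidate
  feature and the response are discretised into up-to-`n_bins` quantile bins
  over the node's rows; the feature minimising the p-value of the chi-square
  independence test between feature bins and response bins wins, ties
  breaking to the lowest column index. The test decouples predictor choice
  from the number of potential split points, removing the selection bias of
  exhaustive-search CART toward many-valued features. `n_bins = 4`
  (quartiles) is the default; the source names the test but not the
  discretisation. Degrees of freedom use only non-empty bins.
- **Split-threshold choice.** On the selected predictor, the threshold
  minimising the summed child SSE over all admissible midpoints (both
  children ≥ `min_samples_leaf`, default 5). Only predictor *selection* is
  specified by the source; variance-reduction thresholds are the
  conventional completion.
- **Leaves** store the mean training age; a forest prediction is the
  arithmetic mean over trees, hence always inside the training-age range.
- **Features** are the screened panel's methylation values plus sex encoded
  0/1; with two levels, the categorical subset split reduces to one binary
  split, so sex needs no special machinery. All features are candidates at
  every node (no per-node feature subsampling): the curvature test already
  de-biases selection, and the source describes testing "each predictor".
- **Invariance.** Quantile bin edges are taken as order statistics
  (`method="lower"`), making binning — and therefore predictor selection —
  exactly invariant under strictly increasing transforms of any feature.
- **Serialisation.** Models round-trip through a versioned JSON schema with
  bit-identical predictions.

Node statistics are vectorised across candidates (a single contingency
`bincount` and one chi-square tail evaluation per node), which keeps a
287-donor, 21-feature tree at ~10 ms and a 500-run × 10,000-tree protocol
within reach on one CPU; tests and the acceptance script use documented
reduced profiles (e.g. 100 runs × 200 trees) that are configuration
choices, not silent substitutions.

## The synthetic-cohort generator

No real cohort is distributed, so the generator stands in for it with the
simplest model consistent with the analysis assumptions:

    meth = clip(intercept + slope·age + offset(population) + N(0, noise_sd), 0, 100)

- **Linearity.** The analysis fits linear regressions and Spearman
  correlations only, so trajectories are linear — no logistic/saturating
  option in this version.
- **Noise** is Gaussian, homoscedastic per CpG and independent across CpGs
  and donors. Real methylation data are heteroscedastic, bounded-skewed near
  0/100 and correlated across neighbouring CpGs; none of that is simulated
  (cross-CpG correlation is an extension point, default off). Clipping to
  [0, 100] happens after noise addition; the clipped fraction is recorded on
  the cohort (`data.attrs`) and logged as a warning above 1 %. Under the
  default scenarios clipping is essentially absent.
- **Populations.** German-like: n = 368, 203 F/165 M, ages 1/12–94 years.
  Japanese-like: n = 89, 55 F/34 M, ages 8–87. Ages are piecewise-uniform
  over the segments cut at 10 and 65 years, with segment weights chosen so
  that *exactly* 287 German-like and 83 Japanese-like donors fall in
  [10, 65] (largest-remainder allocation per segment; out-of-window mass is
  split across the two tail segments proportional to their length). The
  source reports only ranges and the in-window counts, not distribution
  shapes; piecewise-uniform with exact in-window occupancy reproduces the
  analysis sample sizes deterministically, which a plain uniform cannot.
  Sex labels are assigned by exact proportion (largest remainder) and
  shuffled.
- **Slopes and intercepts** are generic anchors by direction — rising sites
  (20 %, +0.5 %/yr), falling sites (65 %, −0.35 %/yr), with a gentler
  (30 %, +0.4 %/yr) anchor for the noisiest rising site so its large
  calibrated noise cannot clip. Magnitudes are in the range reported for
  buccal-swab pyrosequencing panels; only the noise-to-slope ratio matters
  for every statistic the pipeline computes.
- **Noise calibration** (`calibrate_noise`) finds, by bisection against a
  Monte-Carlo Spearman estimate (n = 4000, fixed internal seed, common
  random numbers so the objective is smooth and monotone), the residual SD
  whose simulated |R| matches a target. Default-scenario targets are the
  panel's German-column reference correlations, calibrated under the
  uniform [10, 65] age distribution — i.e. the filtered German-like group
  (n = 287), matching the group for which the reference values are
  reported. Spearman R is range-dependent, so the same noise produces
  higher R over the full 1-month–94-year range; screening is accordingly
  performed inside the analysis window.
- **Scenarios.** `null`: identical generative models for both populations
  (offsets all zero). `two_shifted`: additive offsets of `offset_scale`
  (default 1.0) residual SDs in the Japanese-like population at the two
  sites the reference analysis flagged most strongly — +1 SD at
  *PDE4C* CpG2 and −1 SD at *EDARADD* CpG2. The sign choice is arbitrary
  (the ANCOVA is two-sided) and documented rather than meaningful.
- **Determinism.** One global seed drives keyed per-population substreams
  (`SeedSequence(seed, spawn_key=(pop_index,))`), so each population's draws
  are independent of the other populations' sizes. Identical seeds and
  configurations give byte-identical cohort CSVs.

What passing tests on this generator do **not** show: robustness to batch
effects, bisulfite-conversion variability, cell-composition heterogeneity,
heteroscedastic or correlated noise, or non-linear age trajectories — all
deliberately out of scope. Results on synthetic cohorts characterise the
*procedure* (calibration, power, symmetry), not any real population.

## Numerical choices and degenerate inputs

- Spearman R of a constant vector is undefined and returned as `nan`
  (never silently 0); screening excludes such sites with a logged reason.
- ANCOVA p-values are clamped into (0, 1]; a rank-deficient design (e.g.
  group exactly confounded with age) raises `SingularDesignError`, and the
  popdiff pipeline records that (run, CpG) as missing and excludes it from
  aggregation with a logged count rather than imputing.
- Welch's test on two identical constant groups returns p = 1 (perfect
  balance); the sex test returns p = 1 for identical compositions including
  the degenerate single-sex case.
- Ties in curvature-test p-values and in split-threshold scores break to the
  lowest index / smallest threshold, making trees fully deterministic.
- The forest's bootstrap streams spawn from one `SeedSequence`, so fits are
  reproducible to full precision for a given `random_state`.
- Cohort CSV round trips preserve floats exactly (full-precision repr).

## Known limitations

- The matched-subsample aggregates are dependent across runs by design (see
  above); their sampling distribution under the null is wide, and the
  package intentionally does not present them as calibrated error rates.
- No multiple-testing correction is applied across CpGs; the protocol
  reports raw per-CpG aggregates, and so does the package.
- Matching is rejection-based; a reference group concentrated where the pool
  is sparse can make acceptance practically impossible even when enough
  in-range donors exist, because whole subsets are resampled. This surfaces
  as an explicit matching failure.
- The forest implements no surrogate splits, missing-value handling,
  variable importances or interaction-curvature tests.
- Coordinates in the panel fixture are stored 1-based as published
  (GRCh38.p13); the BED export converts to 0-based half-open. No liftover.
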