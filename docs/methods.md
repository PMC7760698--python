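# Methods

This document describes the statistical procedures implemented in
`ecmetab`, the assumptions behind them, the tunable parameters with
their defaults, and what the synthetic-data generator does and does not
emulate.

## Data model

A `FeatureTable` couples three aligned pandas DataFrames:

- `features` — one row per LC-MS feature: `feature_id`, `neutral_mass`
  (Da), `rt` (min), `mode` (one of `HILIC+`, `HILIC-`, `RPLC+`,
  `RPLC-`), optional `annotation` and `msi_level`.
- `samples` — one row per injection: `sample_id`, `role`
  (`biological` / `blank` / `qc`), `dose_uM` (absent for blanks),
  `experiment_id`, `injection_order`, optional `protocol`.
- `abundance` — features × samples intensity matrix. Missing values are
  explicit NaN and are **never imputed**; every statistic drops NaN
  pairwise and reports how many observations it actually used.

All analyses are stratified by analytical `mode`; features from
different modes are never compared or pooled.

## Blank filtering

For each feature, organoid extracts (biological) are compared against
cell-free ECM blanks:

- **Test** — Welch's unequal-variance *t*-test on log2 abundances, with
  Welch–Satterthwaite degrees of freedom. Non-positive and missing
  values are dropped before the log; a group with fewer than two usable
  values makes the feature *untestable* (p = NaN). The p-value is
  deliberately **not** multiplicity-adjusted at this stage: the filter
  is a screen whose cost asymmetry favors sensitivity, and the
  fold-change cutoff provides the second guard.
- **Effect size** — fold change FC = mean(bio) / mean(blank) on the raw
  scale (a `median` variant exists for the protocol-rating preset).
  Zeros count toward the means even though they are dropped from the
  log-scale test.
- **Labels** — `cell_derived` if FC > `fc_up` and p < `alpha`;
  `ecm_enriched` if FC < `fc_down` and p < `alpha`; otherwise
  `uninformative`. Inequalities are strict: a feature exactly at a
  cutoff is not called.

Defaults: `fc_up = 1.2`, `fc_down = 0.8`, `alpha = 0.05`,
`blank_statistic = "mean"`. The asymmetric cutoffs reflect that a
modest enrichment over a concentrated matrix background is already
meaningful, while the ECM-enriched call is mainly descriptive.
`PipelineConfig.protocol_rating()` switches to median FC > 1, the
variant used when ranking extraction protocols.

## Drift correction and normalization

- **LOESS drift correction.** Pooled-QC injections anchor a per-feature
  trend of intensity versus injection order: a tricube-weighted local
  polynomial (`loess_degree = 2`, `loess_span = 0.75`, at least
  `min_qc = 5` QC points) fit at the QC orders, linearly interpolated to
  every injection, and held constant beyond the first/last QC. Each
  abundance is divided by trend/median(QC), so the correction is
  unit-preserving. Features with too few QCs or a non-positive fitted
  trend are flagged and left uncorrected. The local-polynomial fit is
  solved by least squares on a Vandermonde basis centered at the
  evaluation point; at degree 1 it reproduces statsmodels' lowess to
  machine precision, and degree 2 is the default because monotone
  saturation-type drift has curvature.
- **QC CV filter.** Features with pooled-QC coefficient of variation
  (sample sd, n−1 / mean, raw scale) ≥ `qc_cv_max = 0.20` after
  correction are removed; the boundary is removed, not kept.
- **Sum normalization.** Each sample is divided by its total feature
  sum; empty samples are an error, not a silent pass-through.
- **Control scaling.** For cross-experiment work each feature is divided
  by its per-experiment mean over dose-0 biological samples; features
  with a zero or missing control mean are flagged.

The canonical chain (`preprocess`) is LOESS → CV filter → blank filter →
sum normalization, and returns the feature count after each stage.

## Dose-response screening

- **Correlation.** Spearman's r_s between abundance and nominal dose,
  computed as Pearson correlation of midranks (doses are heavily tied:
  ~5 replicates per dose level). The p-value uses the *t*
  approximation, t = r_s·sqrt((n−2)/(1−r_s²)); this matches
  `scipy.stats.spearmanr` to 1e-10 and extends to the vectorized
  per-feature screen. At least 3 pairs and 2 distinct dose levels are
  required. Note that with replicate-tied doses the attainable |r_s| is
  strictly below 1 even for a perfectly monotone response.
- **Outlier exclusion.** Before correlation, within each
  (experiment, dose) biological group at most one value below 1 % of
  the group median (the smallest) is excluded — a guard against
  failed injections, not a general outlier rule.
- **Multiplicity.** Benjamini–Hochberg within each analytical mode
  (`bh_per_mode = True`), delegated to
  `statsmodels.stats.multitest.multipletests`.
- **Hit rule.** |r_s| > `rs_min = 0.7` and q < `q_max = 0.05`, strict.
- **Consolidation.** Per-experiment hits are grouped greedily by
  nearest mass within ±`mass_tol_ppm = 15` ppm and
  ±`rt_tol_match = 0.2` min, same mode, same direction, at most one
  feature per experiment per group; a consolidated hit needs
  ≥ `min_experiments = 2` experiments. Direction conflicts are logged
  and split, never merged.
- **Joint analysis.** Control-scaled biological abundances from all
  experiments are pooled over the intersecting feature ids and screened
  as one family. Pooling does not increase |r_s| (the population value
  is unchanged) but increases evidence — smaller p at the same effect —
  which is what the package's tests assert.

`DoseResponseModel(tables).fit(joint=True)` wraps the per-experiment
screen, consolidation and joint analysis into one `DoseResponseResults`
object with `per_experiment_frame`, `joint_frame`, `hits_frame` and
`summary()`.

## Annotation

A candidate feature is scored against a `ReferenceCompound` (formula or
monoisotopic mass, optional expected RT, isotope pattern, MS/MS
evidence). Monoisotopic masses are computed with `pyteomics.mass`. Each
available criterion gets a linear-ramp score
s = 100·max(0, 1 − |error|/tolerance):

| criterion        | tolerance                              | weight |
|------------------|----------------------------------------|-------:|
| mass error       | `mass_tol_ppm` = 15 ppm                |    100 |
| retention time   | `rt_tol_match` = 0.2 min               |     60 |
| isotope pattern  | abundance 25 %, spacing 5 mDa          |     50 |
| MS/MS flag       | binary                                 |     20 |

The composite is the weight-normalized mean over the criteria actually
available (e.g. mass 80 and RT 75 with weights 100 and 20 give
(100·80 + 20·75)/120 = 79.17). A match is **accepted** when at least
two of {mass within tolerance, RT within tolerance, composite >
`score_min` = 70} hold; `annotation_rule = "all"` switches to the
stricter conjunctive rule. Targeted lookup (`targeted_match`) selects
the candidate with smallest |ppm error| within a wider
`rt_tol_targeted = 0.7` min window, breaking ties by RT. MSI confidence
levels follow the evidence: authentic-standard RT + MS/MS → level 1,
spectral-database match → level 2.

## Reporting

`classification_summary` tabulates per-mode label counts and the
retained percentage 100·cell_derived/total, rounded **half-up** to one
decimal (Python's bankers' rounding would misreport boundary cases).
`protocol_summary` ranks extraction protocols with the median-FC preset
and the median CV of significant metabolites; `overlap_summary` reports
Jaccard (or min-size) overlap of hit sets; `volcano_table` emits
log2 FC / −log10 p pairs for plotting.

## Synthetic data generator

`SimulationDesign` + `generate_blank_experiment` /
`generate_dose_experiment` produce tables with planted `GroundTruth`
(true class per feature, dose direction, drift curves). What it
emulates:

- Log-normal multiplicative replicate noise, m·exp(z·s − s²/2) with
  s = sqrt(log(1 + cv²)), so the mean and CV are exact by construction.
- Planted cell-derived features: log2 ratio = log2(fc_up·1.25) +
  U(0, 1.5) above the blank level (ratios ≈ 1.5–4.2×), mirrored
  downward for ECM-enriched; the 1.25 separation margin keeps planted
  effects away from the decision boundary so recovery measures the
  test, not the margin.
- Injection-order drift g(x) = 1 + a(x − 0.5) (plus a 0.1a sine term
  for `"linear_sine"`), applied to all injections; QCs are the
  all-sample mean × drift × log-normal noise (CV 0.08), placed every
  5 injections plus first and last.
- Per-experiment batch scale 2^N(0, 0.25); mass jitter 3 ppm and RT
  jitter 0.02 min across experiments (shared feature ids make the
  consolidation step non-trivial); random dropouts are planted as
  ×10⁻³ near-zeros.

What it does **not** emulate: peak shapes or raw spectra (the package
starts from a feature table), correlated co-eluting features, adduct
and in-source-fragment redundancy, retention-time drift within an
experiment, and missingness that is informative beyond low abundance.

Default design — 1000 features (20 % cell-derived, 10 % ECM-enriched),
5 biological vs 3 blank replicates, doses 0/1/10/100 µM with 5
replicates each, 3 experiments — mirrors a typical small organoid study
and is this package's own choice of problem size; replicate CVs of
7–35 % span the plausible instrument-to-biology range.

## Numerical choices and limitations

- Welch's t, Spearman and BH are validated against scipy/statsmodels
  oracles to 1e-10 over 1000 random instances (`scripts/acceptance.py`
  re-runs this check).
- All p-values of 0 arise only from exact monotone configurations;
  constant inputs yield NaN statistics rather than arbitrary values.
- The BH screen controls FDR per mode per experiment; the
  two-of-three consolidation is a heuristic replication filter, not a
  formal combined test.
- The LOESS correction assumes the QC pool tracks biological samples;
  analyte-specific drift that differs between QCs and samples is not
  correctable by design.
- Uncorrected p-values in the blank filter inflate the per-feature
  false-call rate; the downstream dose screen, which is
  multiplicity-controlled, is the inferential stage.
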