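# Methods

## The statistic

For miRNA *i* and tumor sample *j*, the pipeline forms the ratio

    E_ij = log2( F_tumor,ij / mean_j' F_control,ij' )

where the control mean is the NaN-ignoring mean over all control samples
for that symbol, on the intensity ("naturals") scale. The
co-deregulation frequency of symbol *i* is

    f_up(i)   = #{ j : E_ij > 0 }
    f_down(i) = #{ j : E_ij < 0 }       (E_ij = 0 counts toward neither)
    f%        = 100 * f / denominator, rounded half-up to 2 decimals

and symbols are stratified into half-open frequency bands:
100 exactly; [90, 100); [80, 90); [75, 80); below. The direction of a
symbol is whichever tally is larger (a tie is "ambiguous").

**Denominator policy.** Platform content differs across series, so a
symbol is typically unobserved in some samples. Two policies are
implemented: *per-symbol* (denominator = non-missing tumor samples for
that symbol; the default of `scan_codereg`) and *fixed-cohort*
(denominator = total tumor count). The fixed policy is the right one
for claims of the form "down-regulated in 100 % of tumors": under the
per-symbol policy a symbol observed in only a third of the cohort can
reach the 100 % band on a handful of samples by chance. The recovery
benchmarks therefore use the fixed policy; reports can show both.

## Pipeline model and assumptions

Stage order is fixed and validated: background correction → negative
masking → normalization → intensity rescaling → replicate averaging →
testing → ratios → clustering → scan → diagnostics.

* **MBC** computes log2(FG) − log2(BG) cellwise; any non-positive
  channel value gives NaN. Series without a background channel pass
  through as log2(FG), flagged "considered background corrected".
* **Masking** removes strictly negative values only; zeros are kept,
  since very low intensities may still be biologically informative.
* **Normalization** is NaN-aware. Quantile: ranks over each column's
  non-NaN entries, target = across-column mean quantile profile
  linearly interpolated to the column's own count; ties receive the
  average of their target slots, making the map rank-preserving and
  column-permutation equivariant. Loess: M = column − reference
  smoothed over A = (column + reference)/2, span 0.4. Rank-invariant:
  features whose rank differs from the reference rank by ≤ 5 % of the
  finite count form the invariant set; a lowess curve through that set
  maps the column onto the reference scale. The pseudo-reference for
  the latter two is the row-wise median (the sources name the
  algorithms but no reference vector). `compare_normalizations` scores
  methods by mean pairwise Kolmogorov–Smirnov distance between column
  distributions and by the variance of column medians — an explicit
  criterion, chosen here, for the usual observation that quantile
  normalization aligns heterogeneous series best.
* **Naturals are intensity-scale.** Background correction works in
  log2 space, but the "naturals" representation is by definition
  non-log-transformed, so the normalized matrix is exponentiated
  (2**x) before global-mean rescaling. This matters: if the matrix
  stayed in log2 space, the tumor/control ratio would double-log the
  data and compress a 2-log2-unit planted shift to |E| ≈ 0.5, where
  single-sample sign flips destroy 100 %-band membership. On intensity
  scale the shift survives into E at full size (planted markers sit
  near E ≈ −2, matching the magnitudes such scans report).
* **Rescaling** divides every cell by the global mean of non-NaN cells
  (identical to log2-then-exponentiate form); the non-NaN mean is 1
  within 1e-9 afterwards and the operation is idempotent.
* **Testing** uses the classic pooled-variance two-sample *t*-test by
  default (Welch selectable), NaN-aware per symbol; symbols with fewer
  than two finite values in either group are reported untested rather
  than silently skipped. Rows that are numerically constant (spread
  ≤ 1e-9 relative) are flagged degenerate with p = 1 by convention —
  without this tolerance, float-path differences of order 1e-16
  between normalized columns produce junk *t* statistics on effectively
  constant rows. FDR is Benjamini–Hochberg; the selection thresholds
  (p < 0.05, q < 0.05) are configuration values, not constants.
* **Clustering** imputes before distance computations: columns covered
  in ≥ 80 % of rows are kept and remaining NaN replaced by the row
  median (k-means needs complete vectors; the choice is documented
  config, not hidden). The Lloyd loop is written out so the
  within-cluster sum of squares can be asserted non-increasing at every
  iteration; seeding is k-means++, 10 restarts, 100 iterations cap, and
  sklearn's KMeans serves as an independent cross-check in the tests.
  Calinski–Harabasz CH = [B/(k−1)]/[W/(n−k)] selects k over 2..8 by
  default (W = 0 yields +inf, flagged perfect separation). Hierarchical
  sub-clustering uses average linkage by default (single, complete,
  ward selectable) on Euclidean distances.
* **ROC/AUC** uses the Mann–Whitney identity with ties counting one
  half; orientation is auto-selected so AUC ≥ 0.5 and recorded (for a
  down-regulated marker, *low* score predicts tumor). The p-value is
  the asymptotic U test with tie correction. Naive Bayes is Gaussian,
  evaluated by stratified 5-fold cross-validation with a fixed seed;
  within-class variances are floored at 1e-9 and zero-variance features
  flagged. For 2×2 cohort tables, OR = ad/bc, RR = [a/(a+b)]/[c/(c+d)],
  AR = a/(a+b) − c/(c+d), with the Haldane–Anscombe +0.5 correction
  (flagged) when a cell is zero.

A single run seed fans out to per-stage seeds by stable hashing
(CRC-32 of the stage name), so identical configurations give
byte-identical outputs and each stage is individually reproducible.

## The synthetic generator

The generator emulates the structure of a multi-series tumor/control
meta-analysis cohort. Defaults (the reference study conditions used in
the tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| n_series | 3 | series, each on its own pseudo-platform |
| features_per_series / shared | 100 / 50 | union of 200 symbols, 50 shared by all series |
| n_tumor / n_control | 40 / 20 | samples, dealt round-robin across series |
| planted_down_100 | 5 markers | shifted −2.0 log2 units in every tumor |
| planted_up_partial | 2 markers | +2.0 log2 units in 85 % / 76 % of tumors |
| planted_shift | 2.0 log2 units | a strong, recoverable effect |
| noise_sd | 0.5 log2 units | per-cell noise |
| batch_scale_sd | 0.5 log2 units | per-series multiplicative factor |
| background_fraction | 0.01 | background channel level relative to mean signal |
| baseline | log2 ~ N(8, 1.5) | typical array intensity magnitudes |
| n_old_decoys | 3 | extra > 60 y samples exercising the age rule |

Design choices worth knowing:

* **Background is independent of the per-cell signal** (fraction of the
  series mean foreground, with noise tied to `noise_sd`). A background
  proportional to each cell's own foreground would make MBC cancel
  every planted effect. The 1 % level reflects typical array background
  and keeps genuinely expressed features above the masking floor.
* **Planted markers are robustly expressed.** Their baselines are
  remapped into [mean, mean + sd] via the probability transform of the
  same random draw. Both tails are hazardous for a marker that must be
  measurable in every sample: near the detection floor, quantile
  normalization pins tumors and controls to the column minimum; at the
  very top of the scale, a down-shifted marker can remain the column
  maximum and rank mapping erases the shift. A miRNA assayable in 100 %
  of samples on every platform is, by construction, in neither tail.
* Metadata carry gender (with ~10 % missing), age and gestational age,
  sampling mode, diagnosis at three granularities (consistent by
  construction), grade I–IV/CONTROL, and developmental status derived
  from age. Grade-ordered signatures (off by default) add a monotone
  offset along control < IV < I < II < III.

**What the benchmark does and does not show.** Passing the planted
recovery and calibration tests demonstrates that the statistical
machinery is correct under the generator's assumptions: log-normal
intensities, additive log-scale effects, series-constant batch factors,
missingness determined by platform content (not by signal), and
independent cells. Real arrays violate several of these — probe
affinity and dye biases, correlated probes, signal-dependent
missingness, annotation drift across platform generations — so success
here validates the pipeline's logic, not any biological claim about
real cohorts.

## Benchmark sizes and observed behavior

Problem sizes were chosen to exercise the full structure while keeping
any single check in seconds: 200 symbols × 60 samples for recovery
(20 simulated cohorts), 500 symbols × 20 cohorts (10 000 tests) for
null calibration, 20 seeds × 3 planted k values for k-selection.

Under the reference conditions, long-run planted-set recovery is ~97 %
per simulated cohort (measured over 200 cohorts); each failure is a
single tumor sample whose ratio lands marginally above zero (E between
0.001 and 0.06) through the rank-mapping jitter that quantile
normalization adds to per-cell noise. A 20-cohort panel therefore
occasionally reports 90 % recovery. Null calibration is stable: per-test
type-I error 0.046–0.052 at α = 0.05, BH-selected fraction ≤ 0.0003 at
q < 0.05.

## Known limitations

* Loess and rank-invariant normalization are O(columns × lowess); fine
  at hundreds of samples, slow at thousands.
* The ordered-pattern ANOVA treats per-sample cluster means as
  independent observations; it does not model per-series random
  effects.
* No moderated-variance (empirical-Bayes) test, paired designs,
  consensus clustering, or DeLong AUC variance — deliberately out of
  scope.
* Target prediction and GO/pathway enrichment of hits are out of scope;
  the scan stops at the ranked co-deregulation table.
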