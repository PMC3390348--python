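# Methods

This note documents the statistical procedures implemented in
`exprpatterns`, the assumptions behind them, the defaults of the
synthetic-data generator, and the numerical choices made where the design
was genuinely open.

## The analysis model

The package targets grouped expression studies of the kind produced by
bulk microarray profiling of a treatment time course: a gene-by-array
signal matrix over an ordered set of treatment groups (here a home-cage
control followed by 24 h and 72 h of sleep deprivation), collected in two
cohorts, with per-cell detection ("presence") calls.  The analysis chain
is:

1. **Filtering.** Keep probe sets that are annotation grade 'A', map to
   exactly one non-missing gene symbol, and have at least `min_present`
   (default 6) presence calls.  When several probe sets share a symbol,
   one representative is kept: most presence calls, ties broken by higher
   mean signal, then lexically smallest probe id.  The collapsing rule is
   our choice — the upstream convention is not specified — and every stage
   count is reported in a `FilterReport` so the funnel is auditable.  The
   presence-call denominator is parameterized (`presence_columns`) rather
   than hard-coded, because array counts can differ between the
   presence-call universe and the tested design.
2. **Outlier masking.** Cells farther than `k_sd` (default 2) sample SDs
   from their treatment-group mean are treated as missing.  The group mean
   and SD include the candidate cell, and the pass is not iterated.  Note
   this step deliberately trims the within-group tails: downstream SD-based
   effect sizes computed *after* masking are inflated by roughly 15% at
   these group sizes.  A group of two can never lose a cell (|x − mean| is
   exactly SD/√2 there).
3. **Cohort standardization.** Per gene and per cohort, unmasked values are
   z-scored with the cohort's own mean and sample SD, then cohorts are
   recombined.  This removes any additive per-cohort, per-gene background
   shift exactly (to floating point) while retaining each cohort's
   variability.  A gene constant within a cohort cannot be standardized
   there; its cells are set missing and the gene flagged.
4. **Per-gene ANOVA.** Classic unbalanced fixed-effects one-way ANOVA on
   unmasked values; F = MS_between/MS_within on (k−1, N−k) df.  Genes with
   fewer than 2 usable values in any group, or zero total variance, carry
   no statistics and are excluded from multiplicity correction.  The
   significance gate is raw p ≤ α (default 0.05); the Benjamini–Hochberg
   step-up q-values are reported alongside.  "Median FDR" is the median
   q-value among gate-passing genes; the textbook alternative
   α·m/n_significant is also computed (`expected_false_fraction`) because
   published "FDR" summaries are frequently one or the other.
5. **Template matching.** Each significant gene's vector of group means is
   Pearson-correlated with four artificial temporal templates over
   (control, 24 h, 72 h): sustained (0,1,1), transient (0,1,0), delayed
   (0,0,1), linear (0,0.5,1).  The gene is assigned to the template with
   the largest |r|; the sign of r gives the direction (positive =
   increased with deprivation).  The numeric encodings follow the template
   *shapes*; no canonical vectors exist, so they are config-overridable.
   Correlation is over the 3 group means, not the per-chip values (a
   per-chip variant would weight groups by n and change the null
   geometry).  Ties in |r| are broken by template order — a measure-zero
   event for continuous data.
6. **Monte Carlo template null.** Because the four templates carve the
   plane of centered mean-profiles into arcs of different widths
   (sustained/delayed 45°, transient 60°, linear 30° per direction), the
   chance rate of assignment differs per template.  The null is calibrated
   by simulation: 1000 iid standard-normal matrices with the design's
   dimensions, the same ANOVA, and the same assignment, tallying counts
   per (template, direction).  Standard-normal draws are without loss of
   generality: ANOVA p-values and the assignment geometry are
   location/scale invariant.  On the 2167 × 53 design with groups
   (17,16,20) the mean per-direction counts are ≈14 (sustained), ≈18.7
   (transient), ≈13 (delayed), ≈8.8 (linear), total ≈108.4 ≈ α·2167 —
   sustained and delayed differ slightly because the unequal group sizes
   make the three mean coordinates unequally noisy.  Observed counts are
   tested against the null means with an exact upper-tail binomial test.
7. **Overlap analysis.** Two studies restricted to a common background of
   N testable genes, with a and b significant genes, share an observed
   overlap k.  Expected overlap is ab/N and the test is the exact
   upper-tail binomial P(X ≥ k), X ~ Binomial(N, (a/N)(b/N)).  A
   continuity-corrected normal approximation is available
   (`method="normal"`); the two diverge in the far tail.  For the
   reference configuration (N=2167, a=679, b=405, k=189) the exact tail
   is 6.1×10⁻⁸ and the normal approximation 8.7×10⁻⁹ — figures published
   from spreadsheet-era "binomial test" runs tend to fall between these
   variants, and ours bracket the reported 1.55×10⁻⁸.  Signed lists
   additionally yield directional concordance; the m-list same-direction
   test uses expected = N·Π(aᵢ/N)·2^(1−m), assuming independent
   equiprobable signs; and `list_comparison_test` handles studies that
   publish only selected gene lists, via Binomial(n_selected, baseline_p).
8. **Power equalization.** To ask whether a smaller study's discovery
   count reflects a weaker effect or just fewer arrays, subsets of the
   larger study matching the smaller one's array count are drawn without
   replacement (simple random by default, group-stratified by flag; any
   draw leaving a group below 2 arrays is redrawn), the per-subset
   significant-gene counts are histogrammed (default bin width 10), a
   Gaussian A·exp(−(x−μ)²/2σ²) is least-squares fitted to the (bin
   center, frequency) pairs, and the p-value is the fitted curve's
   integrated area below the comparison count over its total area,
   Φ((c−μ)/σ).  The empirical quantile of the raw counts is reported
   alongside as a fit-free check.
9. **Overrepresentation.** The EASE score: a one-tailed Fisher exact test
   with the overlap cell decremented by one, p = P(X ≥ k−1),
   X ~ Hypergeom(N, K, n); k ≤ 1 gives p = 1.  It is conservative —
   always at least the classical Fisher p — and damps categories
   supported by very few genes.  Categories are reported when their
   significant-gene count is within [3, 50].  No multiple-testing
   correction is applied to enrichment p-values by default; a BH column
   is emitted for convenience.

## Synthetic data

`SyntheticSpec` defaults define the emulated study: 2167 genes × 53
arrays in groups of 17/16/20; cohort 1 holding 37/69 of each group's
arrays; a +0.5 noise-SD additive background offset on cohort 2 (the
standardization stage must remove it exactly); 200 genes planted per
template (direction split 50/50) at effect size 2.0 in within-group SD
units; unit noise SD; presence rate 0.9 (genes passing the presence
filter are mostly detected); baseline 8.0 on a log2-intensity-like
scale.  Null genes are iid normal in every group; a planted gene's group
mean is shifted by ±(effect size)·SD·(template value).

What the generator does **not** emulate: probe-level summarization,
intensity-dependent variance, correlated genes, heavy-tailed noise, or
batch effects beyond an additive cohort shift.  Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under its own assumptions, not robustness to real microarray pathology.

`generate_null_matrix` produces the pure-noise matrices for the Monte
Carlo calibration: same rows and columns as the design, all cells
present, single cohort.

## Numerical choices

- SD is the sample SD (n−1 denominator) everywhere.
- Stage order is mask-outliers → standardize → ANOVA; masking before
  standardization keeps single extreme cells from distorting cohort
  moments.
- BH q-values are computed by `statsmodels.stats.multitest`
  (`fdr_bh`); tests verify them against the brute-force step-up
  definition.
- All binomial/hypergeometric tails use the exact scipy distributions;
  upper tails are `sf(k−1)` so that P(X ≥ 0) = 1 holds exactly.
- The Gaussian histogram fit is initialized from the sample mean, sample
  SD, and modal bin height; non-convergence and degenerate histograms
  (fewer than 5 non-empty bins, or zero variance) are errors, not
  warnings.
- Stochastic stages take explicit seeds; the pipeline derives
  per-stage substreams from one master seed and records them in the
  manifest.

## Problem sizes used in the checked examples

The Monte Carlo calibration runs the full 1000 × 2167 × 53 design
(a few seconds, vectorized F statistics).  Resampling and pipeline
examples in the test suite use reduced designs (hundreds of genes, tens
of iterations) chosen so the quantities they check — calibration to α,
determinism, monotonicity — are already stable at that scale.

## Known limitations

- The EASE implementation scores user-supplied gene sets only; it does
  not reproduce kappa-based category clustering or any ontology
  traversal.
- The multiway same-direction expectation assumes independent lists and
  equiprobable signs; published three-study comparisons computed with
  other conventions will differ (ours gives ≈1.61 expected for the
  495/(169,148,63) configuration, where a rounded "1" has been printed
  elsewhere).
- Correlation-based assignment with three groups cannot distinguish a
  template from any positive affine transform of it; effect magnitude is
  carried by the ANOVA and effect-size columns, not by |r|.
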