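# Methods

## Pipeline overview

The pipeline operates on a feature × sample matrix of qPCR cycle-threshold
(Ct) values with per-well quality metrics, and a per-sample table of
covariates and lung-function phenotypes. Stages, in order:

1. **Well QC.** A well is detected only if its amplification score exceeds
   1.24 *and* its Cq confidence exceeds 0.80, both strictly: a score exactly
   at the threshold fails. Failing wells are blanked to missing rather than
   removed, so the detection filter sees a single unified notion of
   missingness. Cells without a QC record count as detected whenever a Ct
   value is present.
2. **Detection filter.** Features detected in fewer than 75% of the
   denominator are dropped. The denominator is `samples` by default (every
   profiled sample, technical replicates included), because the downstream
   permutation analysis is defined over the full sample-level matrix; a
   `subjects` mode (a subject detected if any of its samples is) is provided
   since either convention is defensible and they differ only at the margin.
3. **Replicate handling.** `keep_all` (default) leaves technical replicates
   as separate columns, reproducing the full matrix dimensions;
   `mean_per_subject` averages non-missing Ct per (feature, subject) and is
   the statistically safer choice when downstream models assume independent
   rows. Replicate agreement is quantified as the Spearman rank correlation
   across features shared by both profiles of a pair (pairs sharing < 3
   features get a missing correlation).
4. **Normalization.** Sample-wise quantile normalization to the mean of the
   samples' order statistics: in a complete matrix each column's sorted
   values are replaced by the across-column mean of sorted values, so all
   columns share one distribution while each column's internal ranking is
   untouched. Per-feature rank normalization (average ranks, ties averaged)
   is available as a robustness variant for outlier-sensitive fits.
5. **Association.** Per feature, ordinary least squares of phenotype on Ct
   over pairwise-complete cases; significance by 95%-CI exclusion of zero
   (equivalent to the two-sided t test at α = 0.05; an endpoint exactly at
   zero counts as containing it). Benjamini–Hochberg adjustment across the
   tested features is reported alongside; a Storey-style q-value is
   available behind `method="storey"` but BH is the default because it is
   deterministic and assumption-light. Multivariable fits add age, sex
   (indicator, female = 1) and height, and report the CI and p-value of the
   Ct coefficient with df = n − (#coefficients); covariates that are
   constant over the complete cases are dropped so the fit degenerates
   cleanly to the simple model. Sex-stratified calls refit per stratum with
   the same rule. The fetal variant uses gestational age (days post
   conception) as the response over fetal-lung samples.
6. **Permutation FDR.** Each iteration draws one uniform random permutation
   of the phenotype vector (Ct fixed), reruns the CI test for every feature,
   and records the significant count. Permutations are sampled with
   replacement — standard Monte-Carlo practice — and the iteration count is
   exactly `n_iter` (default 10,000). The FDR estimate is (median or mean
   count) / (observed significant count); when nothing is observed
   significant the estimate is reported missing, not zero. Labels are
   permuted at the sample level by default (matching the full-matrix
   convention); a subject-level mode keeps replicate pairs tied together.
7. **Cross-reference.** Pure-table joins: literature flags (`Y` for ≥ 1
   prior study, `Y2` for ≥ 2), target-gene/GWAS-trait intersection, and the
   overlap report of the significant, male-only, female-only and
   fetal-associated sets with percentages re-derivable from the membership
   lists. Feature matching is exact string equality, optionally after
   trimming the `hsa-` species prefix.

## Numerical choices

- **Missing-data quantile normalization.** For columns with missing cells,
  the value at within-column rank r among m non-missing values sits at
  p = (r − 0.5)/m and is mapped through the reference quantile function —
  the mean of all columns' empirical quantile functions evaluated on a
  common grid of size equal to the largest column count — by linear
  interpolation. This reduces exactly to the complete-data definition when
  nothing is missing. Ties receive the mean of the reference values their
  tied ranks would map to. Idempotence is exact for complete matrices; with
  missing cells a second application can shift values slightly because the
  interpolated reference is re-estimated, so the idempotence property is
  asserted on complete data only.
- **Vectorized permutation engine.** The per-iteration CI test is computed
  via the identity t = r√(n−2)/√(1−r²): a feature is significant iff its
  squared correlation with the permuted phenotype exceeds
  t²crit/(n−2+t²crit), with n and the critical value precomputed per feature
  from its complete-case mask. The test suite asserts exact agreement
  between this path and the per-feature statsmodels fit, including under
  missingness, and against exhaustive enumeration of all permutations on
  small inputs.
- **Missing Ct** is handled by per-feature pairwise deletion throughout;
  fits with fewer than 3 complete cases or constant Ct are flagged unusable
  with a reason, never silently dropped.
- **Ct bounds** [0, 45] are enforced at read time (45 being the
  conventional maximum cycle count); the NA token on disk is `NA` (empty
  cells also read as missing).

## Synthetic cohort

The generator emulates the study design the pipeline expects:

- 160 subjects, of whom the first 13 are profiled twice (173 samples);
  male fraction 0.544. Phenotypes are Gaussian at the cohort moments
  FEV1/FVC 78.73 ± 8.71, FEV1% 93.35 ± 14.72, FVC% 106.13 ± 13.51; age
  8.83 ± 2.12 years. Height is 80 + 6·age + N(0, 5) cm — a device to make
  the covariate-adjusted model exercisable, with no claim of anthropometric
  realism; raw volumes are scaled from height and the percent-predicted
  values so that FEV1/FVC ≡ 100·FEV1(L)/FVC(L).
- 738 assayed features: 108 "detectable" with mean Ct uniform on [18, 32],
  the rest centered on [34, 40], all with feature noise sd 1.0 Ct and
  exchangeable block correlation (block 6, ρ 0.25) across features. Latent
  Ct above the detection limit (33) is censored to missing — a
  missing-not-at-random mechanism mimicking low-abundance dropout — and the
  accompanying well QC scores are drawn below the gates for censored wells
  and above them otherwise, so QC and censoring agree. These choices make
  the 75% filter retain ≈ 108 features by construction.
- Technical replicates add N(0, 0.25) Ct to the subject's latent profile,
  which yields replicate rank correlations well above 0.9 across 108
  features (the across-feature spread of ~4 Ct dominates the 0.25 Ct
  replicate noise).
- Planted effects shift latent Ct by `slope_ct` (Ct per phenotype-SD) times
  the standardized phenotype, optionally in one sex only. The truth record
  stores both this generative coefficient and the implied phenotype-on-Ct
  regression slope sd_y·b/(b² + σ²), so recovery tests compare like with
  like. Slopes of 0.12–0.35 Ct/SD imply regression slopes of roughly 1–2.6
  phenotype units per Ct at sd_y = 8.71, the scale of the reported serum
  associations.
- The fetal generator draws ages uniform on [67, 115] days post conception
  (n = 30) and plants linear Ct–age trends with the analogous truth record.
- The block-correlation default is a modeling choice (no empirical
  inter-microRNA correlation estimate is available for this panel) and is
  exposed in the parameters.

What the generator does *not* emulate: plate/batch effects, heavy-tailed or
skewed phenotype distributions, realistic inter-feature correlation
structure beyond exchangeable blocks, measurement error in spirometry, or
the actual identities of the study's microRNAs (synthetic features carry
`syn-miR-*` ids). Passing tests therefore demonstrate the statistical
machinery — calibration, power, coverage, FDR arithmetic — under the stated
design, not biological reproduction of the original measurements; the
published per-microRNA effect sizes are not reproducible without the
deposited expression data.

## Annotation fixtures

The package ships small TSV transcriptions of the published report tables
(the 22/4/8 association panels, the sex-stratified calls, the target-gene
and GWAS-trait maps, the 15-study roster). The per-study literature
membership is *synthetic*: only per-feature study counts (the Y/Y² flags)
are printed in the main report, so the fixture assigns features to
pseudo-arbitrary studies reproducing those counts, and says so in its
header. One trait-table omission (CEBPB, listed as a GWAS-linked target but
absent from the printed trait table) is patched with the two traits shared
by every other gene so the printed per-panel target counts reproduce; the
fixture header notes this.

## Problem sizes and determinism

Default analyses run at the full study scale (738 × 173 matrix, 10,000
permutations); the vectorized permutation engine makes this a
seconds-not-minutes computation, so no stage is scaled down. Property
checks use 600 replicate cohorts for CI coverage, 1,000 random regressions
for the CI/t-test equivalence, 20,000 sampled permutations against the
exhaustive 24-permutation oracle, and exhaustive grids for the BH oracle.
All randomness flows through named integer seeds (numpy `default_rng`);
identical seeds give bit-identical cohorts, permutation counts, and
pipeline artifacts.

## Known limitations

- The CI-exclusion rule is nominal-level only under the per-feature model;
  with technical replicates kept as independent columns (`keep_all`) the
  effective sample size is overstated, which is why `mean_per_subject` and
  subject-level permutation are provided.
- The missing-data branch of quantile normalization is a deterministic
  convention, not a reconstruction of any particular instrument vendor's or
  Matlab routine's undocumented behavior.
- Storey q-values use the cubic-smoother π₀ estimate and may be unstable
  for very short p-vectors; BH is the default for exactly this reason.
- The fetal analysis takes whatever sample table it is given and does not
  arbitrate between subject-level and sample-level accounting of the
  fetal-lung collection.
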