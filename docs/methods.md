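# Methods

`fluprop` implements a word-property analysis of verbal-fluency performance
for dementia research, together with the synthetic cohorts used to validate
every stage. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic validation does and does not
establish about real data.

## Word properties

Each uttered word is scored on six psycholinguistic variables:

- **frequency** — log10 occurrences per million tokens, taken from the
  lexicon as supplied (no internal transform; zero/negative raw frequencies
  are the lexicon supplier's concern);
- **granularity** — conceptual specificity, the number of edges on the
  shortest path from the word's concept to the root hypernym `entity` in a
  hierarchical taxonomy. "Number of nodes between a word and the root" is
  ambiguous between edge count and interior-node count (edges − 1); the
  edge count is used because it is well defined for direct children of the
  root and matches the convention that depth-3 words are more general than
  depth-10 words. Polysemous forms take the **minimum** depth across
  senses: deterministic and requiring no sense disambiguation. Users who
  prefer max- or first-sense behavior can post-process
  `TaxonomyGraph.senses`;
- **phonological neighborhood** — the number of lexicon words whose phoneme
  sequence differs by exactly one substitution, insertion, or deletion (no
  transpositions). Homophones (distance 0) are not neighbors. The count is
  built with a wildcard/deletion index rather than an all-pairs scan. If a
  lexicon carries no phoneme data at all it is treated as graphemic
  (characters stand in for phonemes, logged); in a mixed lexicon, forms
  without phonemes get a missing neighborhood instead of silently mixing
  units;
- **length** — phoneme count;
- **familiarity**, **imageability** — 1–7 normative ratings.

Lookup keys are lowercased and accent-stripped (NFKD) because orthographic
mismatch between transcripts and lexicons is the dominant failure mode;
original forms are preserved. A word missing any one property contributes
to the remaining properties: missingness is per property, never
all-or-nothing.

## Response validity

Valid-response counts follow the standard fluency scoring: within each
participant × task trial, digit-bearing tokens are rule violations, exact
normalized duplicates after the first occurrence are repetitions, and
unintelligible markers are discarded from all property analyses (retained
in raw records for audit). Proper-name and morphological-family judgments
are examiner decisions in practice, so they enter through a per-study
invalid-word list rather than an automated heuristic — the package refuses
to guess a language model where studies use humans.

## Distributional features

Each property is summarized per participant by seven statistics: mean,
median, SD (n−1), min, max, moment skewness g1 = m3/m2^1.5, and excess
kurtosis g2 = m4/m2² − 3. The bias-uncorrected moment estimators are the
simplest convention; skewness and kurtosis are missing when n < 3 or the
variance is zero. 6 properties × 7 statistics = 42 features. By default the
two tasks' words are pooled before featurization (the 42-column classifier
input); `task_mode="per_task"` yields 42 per task and feeds the group ×
task analyses. Valid counts per task ride along but are never classifier
input. Per-participant counts of property-missing words are recorded so
that missingness itself can be compared across groups with the same ANCOVA
machinery.

Trimming variants reproduce the usual robustness checks: `all_responses`
(primary), `valid_only`, and `valid_outlier_trimmed`, which removes
word-level values beyond k = 3 SDs from the group's pooled word-level mean
within property × task. Note that in tiny groups no point can exceed
3 sample SDs (the largest attainable |z| in a sample of n is (n−1)/√n), so
the trim only bites in realistically sized word pools.

## Mixed ANCOVA

Group comparisons use a 2 (group, between) × 2 (task, within) mixed ANCOVA
with sex, age, and education as additive fixed covariates (no
covariate × factor interactions), Type III sums of squares, sum-to-zero
contrasts, and partial eta squared per term. With a two-level within
factor the model decomposes exactly: between-subject effects are an
ordinary ANCOVA on each subject's task mean; the task and group × task
effects are an ANCOVA on each subject's task difference, in which additive
covariates cancel, leaving intercept + group (denominator df N − 2). The
implementation reproduces an independent linear-mixed-model reference
(random subject intercept, Type III, Satterthwaite) to 1e-6 on a frozen
fixture, including the within-stratum error mean square. η_p² is computed
from sums of squares within each error stratum, not back-derived from F.
Tukey HSD post-hocs compare the four group × task cells with
Tukey–Kramer standard errors and the studentized-range distribution;
Cohen's d uses the two cells' pooled SD.

## Classification

Subject-level discrimination uses logistic regression (L2, C = 1.0,
intercept, lbfgs, iteration cap 1000 — pinned so behavior does not drift
with library defaults) inside stratified 5-fold cross-validation repeated
over random partitions (1000 by default). Per fold, min–max scaling and
then KNN imputation (uniform weights, K = 5, Euclidean over observed
coordinates) are fitted on the training folds only and applied to the test
fold, whose scaled values are clipped to [0, 1]; observed cells are never
altered. Out-of-fold probabilities are pooled within an iteration for the
AUC and for accuracy at a 0.5 boundary (pooling is stabler than per-fold
AUC at n ≈ 60); importances are mean absolute coefficients over all fold
models; each subject's output score is the across-iteration mean of its
out-of-fold probability. One caveat documented deliberately: under the
null (permuted labels) pooled cross-validated AUC centers slightly below
0.5 (≈ 0.43 at n ≈ 60 with 42 noise features) — the well-known pessimistic
bias of out-of-fold scores — and single permutations scatter by ± 0.08, so
chance-level claims should be made on means over permutations.

## Correlation batteries

Measure × target correlations are computed on pooled samples (a patient
group collapsed with controls, to increase variance), Spearman by default;
an `auto` policy uses Pearson only when Shapiro–Wilk accepts normality of
*both* variables at α = 0.05. Each declared battery is
Benjamini–Hochberg-corrected as one family. Partial correlations
residualize both variables on the controls by OLS (after rank
transformation for the Spearman variant) and lose one denominator df per
control; they match an independent reference implementation to 1e-9
including p-values.

## EEG connectivity

Recordings are band-passed (beta, 13–30 Hz, as the default band of
interest) and cut into non-overlapping 1000-ms segments. The zero-phase
band-pass is implemented in the frequency domain as multiplication by the
squared magnitude response of an order-4 Butterworth design: this has the
same amplitude response as forward–backward filtering but exactly zero
phase and no start-up transients, so a strictly in-band periodic signal
passes through unchanged — which is what makes the analytic check below
exact. Wrap-around artifacts for non-periodic signals are confined to the
recording edges and suppressed by excluding the first and last 100 ms of
each segment's analytic-phase series.

The phase-locking value between channels a and b is
|mean_t exp(i(φa − φb))| with instantaneous phases from the Hilbert
analytic signal, averaged over segments: 1 for a constant phase difference,
O(T^−1/2) for independent phases. Two signals with a constant quarter-cycle
offset yield PLV = 1 to machine precision (the package's analytic
self-check).

Group comparisons use a nonparametric cluster-based permutation test:
per-edge two-sample t-tests (pooled variance by default; Welch available)
thresholded at p_con = 0.05 two-tailed; supra-threshold connections
sharing a sensor form clusters (connected components in sensor space —
the natural adjacency for connectivity matrices); the cluster statistic is
its connection count; and each observed cluster is referred to the
permutation null of the **maximum** cluster statistic (family-wise error
control) with the (count + 1)/(n_perm + 1) convention, so p-values are
never zero. Because the cluster statistic is a small integer, the null
distribution is heavily tied and the test is conservative: measured
family-wise error under the null is ≈ 2–3% at α = 5%, i.e., p-values are
uniform-dominated rather than exactly uniform. This is a property of
count-valued cluster statistics, not of the implementation.

## Synthetic data

The generators produce every input the pipeline consumes, with the
dependence structure the analyses assume. They are pure functions of
(spec, seed).

**Lexicon.** 2000 words by default; Zipf frequencies (exponent 1.2, top
frequency 3 × 10⁴ per million); familiarity, imageability, phoneme length,
and taxonomy depth tied to the frequency latent through a Gaussian copula.
The spec's correlations are *Spearman* correlations (converted to latent
Gaussian correlations via 2·sin(πρ/6)) because the marginal transforms are
monotone and rank correlations survive them exactly; defaults:
frequency–familiarity 0.6, –imageability 0.4, –length −0.5, –granularity
−0.4. The taxonomy is a random rooted tree (internal skeleton plus one
leaf per word, depths 2–9); 5% of words get a second sense. Familiarity,
imageability, and frequency values are deleted at 5% to exercise the
ignore-missing policy and KNN imputation.

**Cohorts.** Default group sizes 32 (AD-like), 32 (bvFTD-like), 27
(controls), with demographic and cognitive-score distributions matching a
typical three-center dementia cohort (ages ≈ 76/69/72, education ≈
12/13/14 years, MoCA ≈ 15/18/26, IFS ≈ 14/16/21). A latent severity
(group mean 1 for patients, 0 for controls, SD 0.25) drives:

- per-task valid counts: base 18 ± 4 minus a deficit of 1.9 (AD-like) or
  1.2 (bvFTD-like) count-SDs at severity 1;
- word choice: softmax over a per-word utility Σp effect_p × severity ×
  z_p(word). The AD-like profile plants +0.8 SD frequency and −0.8 SD
  granularity in both tasks and +0.8 SD neighborhood in the semantic task
  only; the bvFTD-like profile plants nothing. Effects are stated in units
  of the between-participant SD of property means; the conversion constant
  (`utility_gain = 0.28 ≈ 1.2/√18`) was calibrated once so a lone 0.8 SD
  frequency plant realizes d ≈ 0.8. When all three correlated effects are
  planted together, realized effects inflate to ≈ 0.9–1.1 SD because the
  properties reinforce each other through the copula — as they would in
  real lexicons;
- IFS: linear in severity with noise set so the pooled patient+control
  correlation is 0.7 (`ifs_link`); MoCA analogous.

Invalid responses are injected at rates 4% (repetitions), 1% (digit
tokens), 1% (unintelligible markers).

**EEG.** 32 channels, 256 Hz, 20 s per subject, 16 + 14 subjects — a
deliberate desk-scale reduction of a high-density resting-state protocol;
the cluster test's calibration is established by simulation at these sizes
rather than by matching a particular montage. Channels mix unit-variance
noise with shared band-limited sources: all channels couple to a global
source at 0.2; a planted 10-sensor cluster couples to its own source at
0.75, reduced by 50% in the affected group. PLV between generated channels
rises monotonically with the mixing coefficient.

**What passing tests show — and don't.** The synthetic cohorts have, by
construction, linear severity links, Gaussian copula property dependence,
exchangeable subjects, and no phonemic/semantic category structure in the
lexicon (both tasks sample the same word pool; task selectivity enters only
through effect flags). Passing calibration and recovery tests therefore
demonstrates that the *statistical machinery* is correct and adequately
powered at realistic sizes — not that real fluency data satisfy these
generative assumptions, and not that the planted effect sizes equal real
disease effects.

## Numerical and operational choices

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; fixed-seed reruns are bit-identical
  end-to-end (generators, classifier partitions, permutation tests).
- Listwise deletion in the ANCOVA (a subject missing either task value or
  any covariate) is logged with the count of removed subjects; fewer than
  3 complete subjects per group, constant outcomes, degenerate post-hoc
  cells, collinear controls, and empty clusters raise errors rather than
  returning silent NaNs.
- Simulation sizes in the test suite and acceptance script (400 null
  cohorts, 200 power cohorts, 500 × 200-permutation EEG replicates, 40
  label permutations) are the package's choice of desk-scale precision:
  binomial tolerance bands use 2.9 standard errors at those counts.
- Classification defaults (5 folds, 1000 iterations, K = 5, C = 1.0) and
  the permutation count (1000) are configuration, not constants; the CLI
  exposes them.

## Known limitations

- Granularity depends entirely on the supplied taxonomy's depth
  conventions; cross-taxonomy comparisons of absolute depths are not
  meaningful.
- The neighborhood count treats the lexicon as the population of
  candidates; small lexicons understate true neighborhood sizes.
- The ANCOVA is exact only for the 2 × 2 design; more within-levels would
  need a different error decomposition (or a mixed model).
- No artifact correction, channel interpolation, or re-referencing is
  provided for EEG; inputs are assumed preprocessed.
- The pipeline consumes precomputed fMRI network-strength values; no
  imaging preprocessing or voxelwise statistics are included.
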