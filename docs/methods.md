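# Methods

## The selection model

EFS-GINI treats feature selection for high-dimensional labeled matrices as a
three-stage consensus problem. The underlying assumptions are:

* redundancy is monotone — if two features carry the same information their
  rank correlation is near ±1, so Spearman's r_s (Pearson correlation of
  average ranks, reducing to 1 − 6Σd²/(n(n²−1)) without ties) detects it
  without distributional assumptions;
* a univariate ANOVA F statistic is a cheap, high-recall shortlist: truly
  informative features rarely have *no* marginal effect, so the expensive
  instance-based filters only need to see the shortlist;
* different filter families err differently — mutual information is
  threshold-free but discretization-dependent, relief-family weights see
  feature interactions but degrade as class-independent features dominate
  the distance metric — so features selected by *all* of them are trusted
  outright, and the disputed remainder is arbitrated by an embedded
  criterion (CART Gini importance) evaluated jointly rather than
  univariately.

The combinator keeps the intersection F₀ of the four stage-2 subsets, grows
one deterministic CART tree on the training data restricted to the disputed
candidates D, accumulates each feature's impurity reduction
(node-fraction-weighted Gain, normalized to sum to 1), and tops F₀ up to
exactly k features. If every filter nominated the same subset, no tree is
built. If the tree cannot split informatively (zero total gain), candidates
are ordered by mean rank across the four stage-2 rankings instead — a
deterministic, information-bearing fallback.

Classification quality is measured with a heterogeneous soft-voting ensemble
(decision tree, Gaussian naive Bayes, calibrated-probability SVM, kNN,
100-tree random forest) so that no single inductive bias dominates the
assessment of a feature subset.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `spearman_threshold` | 0.9 | drop a feature when \|r_s\| with an earlier kept feature reaches this |
| `k_final` | ⌈1% of original features⌉ | size of the final selection (count or fraction) |
| `stage1_pool` | min(survivors, 10·k_final) | F-test shortlist size handed to stage 2 |
| `n_bins` | 8 | equal-frequency bins for the MI estimator |
| `n_neighbors` | 20 | ReliefF hit/miss neighbors per class (clamped with a warning if a class is smaller) |
| `test_fraction` | 0.4 | held-out share of the stratified split |
| `whole_data_prep` | off | fit the Spearman filter and standardizer on the whole matrix before splitting |
| `unweighted_gain` | off | accumulate raw per-node gains instead of node-fraction-weighted gains |
| `rf_estimators` / `knn_neighbors` / `svm_kernel`, `svm_c` | 100 / 5 / rbf, 1.0 | base-learner settings |

The shortlist factor of 10 leaves the stage-2 filters a candidate set an
order of magnitude larger than the final selection — large enough that they
do real work, small enough that relief-family distance metrics are not
swamped by irrelevant dimensions (see below). The final-size rule is
computed on the feature count *before* any filtering, so the same data
always yields the same k.

All randomness (split, base learners) derives from one master seed through a
fixed seed-sequence scheme; a repeated run is byte-identical in both the
selection and the evaluation report (wall-time excepted).

## Pipeline order and leakage

By default every fitted quantity — the redundancy filter, the standardizer
(μ and population σ per feature), all rankings, the tree, the ensemble — is
computed on the 60% training partition only and applied unchanged to the
held-out 40%. `whole_data_prep` instead preprocesses the full matrix before
splitting, matching the common whole-dataset protocol; it is provided for
comparability, not recommended. Standardization is the plain z-score; it
does **not** confine values to [−1, 1] (no bounded scaling is applied
anywhere), and the stratified split is seeded with per-class half-up
rounding repaired so both partitions retain every class.

## Estimator conventions

* **Spearman filter**: features are scanned in column order; a feature is
  dropped on the first already-kept partner with |r_s| ≥ threshold (earliest
  partner recorded). Absolute value is used — a perfect negative correlation
  is just as redundant. Constant features have r_s defined as 0 against
  everything; they survive this stage and die of zero F/MI scores later.
* **F-test**: features separating the classes with zero within-class
  variance get F = +∞ and rank first, ordered among themselves by
  between-group sum of squares; features with zero between-group variation
  (including constants) score 0. Sums of squares below 1e−12 of the total
  are treated as zero.
* **Mutual information**: equal-frequency binning into ≤ `n_bins` bins
  (duplicate quantile edges merge), then the plug-in estimate with base-2
  logs — scores are in bits; empty cells contribute 0. The plug-in
  estimator is biased upward at small n; scores are used only for ranking.
* **Relief family**: Manhattan distance on range-normalized features, all n
  instances visited, misses weighted by P(class)/(1 − P(own class)), diffs
  range-normalized so weights lie in [−1, 1] and are invariant to affine
  rescaling of any feature. SURF and SURF* use the threshold T = mean of
  all pairwise distances; an instance at exactly T joins neither zone, and
  updates are normalized by the realized per-zone neighbor counts.
* **Rankings**: descending score, ties broken by ascending column index —
  every ordering in the package is total and deterministic.
* **CART**: splits at midpoints of consecutive distinct sorted values
  ("≤ threshold" goes left); growth stops on purity, fewer than 2 samples,
  or no gain above 1e−12. A candidate (feature, threshold) replaces the
  incumbent only when its gain is more than 1e−12 better, scanning features
  then thresholds in ascending order, so mathematically tied splits resolve
  to the lowest feature index and lowest threshold. No pruning, no feature
  subsampling — the tree is a ranking device, not a classifier.
* **Metrics**: macro averages are unweighted over classes; a class with an
  empty precision/recall denominator (or P + R = 0 for F1) contributes 0.
  Probability columns follow the training labels' first-appearance order.

## The synthetic generator

`make_synthetic` emulates the target regime: balanced classes, a small set
of informative features whose class means are a seeded permutation of
equally spaced levels scaled by `effect_size` (within-class sd 1), one or
more redundant features per informative source (random affine transform —
slope possibly negative — plus Normal(0, 0.1) noise, keeping |r_s| with the
source ≈ 0.999), and i.i.d. Gaussian noise for everything else. The
per-feature level permutation matters: it decorrelates informative features
from one another (worst-case pooled correlation ≈ 0.83 at effect 2.0 when
two features share a permutation, below the 0.9 gate), so only the planted
copies are redundant by construction.

What the generator does **not** emulate: heavy-tailed and count-valued
expression distributions, probe/batch effects, correlated noise blocks,
class imbalance, label noise, and interaction-only (marginal-effect-free)
signal. Passing recovery tests therefore demonstrates that the machinery
finds additive Gaussian class structure under heavy noise dilution — not
that it resolves any particular biological contrast.

The default study conditions are 200 samples × 2000 features, 10
informative features with one redundant copy each, 4 classes, effect size
2.0 — a few-samples/many-features ratio typical of the expression
benchmarks this class of method targets, with 20 seeded replicates
summarized by medians. These sizes keep a full study (pipeline plus five
baselines per replicate) under a minute on one CPU.

## SURF* and the value of staging

A deliberate finding documented here because it shapes the design: the
far-zone sign inversion that lets SURF* see interaction structure (far
same-class pairs with large feature differences) systematically *penalizes*
a lone main-effect feature once many class-independent features dominate
pairwise distances — different-class pairs are slightly farther apart, so
the inverted far zone accumulates negative weight exactly on the informative
feature. Empirically its informative-vs-noise separation on the default
generator is positive at shortlist scale (~200 features) and turns negative
by ~2000 features, and as a standalone selector on thousands of raw features
it can fail outright. The three-stage design is the remedy: stage 2 only
ever scores the F-test shortlist, where all four filters separate planted
signal from noise. The single-filter SURF* baseline intentionally skips the
shortlist and shows the unstaged behavior.

## Known limitations

* The pairwise Spearman matrix is O(p²) in memory (~0.3 GB at p = 6000);
  very wide matrices need blocking that this implementation does not do.
* Dense matrices only; no sparse support, no missing-value handling (loads
  fail loudly instead).
* The plug-in MI estimator and the single unpruned CART tree are
  high-variance at very small sample sizes; they are used for ranking, never
  for effect-size interpretation.
* A single seeded split evaluates each configuration; repeated-split
  uncertainty is available only by varying the seed externally (as the
  recovery study does).
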