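# Methods

`antioxseq` classifies protein sequences as antioxidant (positive) or
non-antioxidant (negative) from sequence composition alone, through a
four-phase pipeline: descriptor extraction, training-set rebalancing,
MRMD feature selection, and a vote-based random forest evaluated on an
untouched test split. This note records the models, the parameters that
matter, the numerical conventions, and the limits of what the synthetic
benchmarks can show.

## Sequence descriptors

**CKSAAP** (composition of k-spaced amino-acid pairs). For a sequence
`P = A1 A2 ... AN` and gap `k`, every ordered residue pair separated by
exactly `k` intervening residues is counted; the frequency of pair
`(a, b)` is `n(a,b) / (N - k - 1)`, the denominator being the number of
gapped windows (`N - 4` at the default `k = 3`). One gap value gives
20 x 20 = 400 features that sum to exactly 1 — this conservation is
asserted as a property test. Pair `(a, b)` maps to column
`20 * rank(a) + rank(b)` in the fixed alphabet order
`ACDEFGHIKLMNPQRSTVWY`; the descriptor literature does not fix an
ordering, so this lexicographic convention is pinned here and everywhere
column indices matter. Multiple gaps may be concatenated
(`gap=[1,2,3]`), but the default is the single `k = 3` block: 3-spaced
pairs are the configuration known to discriminate antioxidant proteins,
and it keeps the combined set at 743 columns.

**Conjoint triad (CT).** The 20 residues are collapsed into 7 classes
by dipole and side-chain volume — 1 {A,G,V}, 2 {I,L,F,P}, 3 {Y,M,T,S},
4 {H,N,Q,W}, 5 {R,K}, 6 {D,E}, 7 {C} — and every consecutive 3-residue
window contributes one class triad, giving raw counts `v_1..v_343`
(triad `(c1,c2,c3)` at index `(c1-1)*49 + (c2-1)*7 + (c3-1)`; the sum of
raw counts equals `N - 2`). Counts are normalized as

    d_i = (v_i - min v) / max v

which is the descriptor's published form and guarantees `d_i` in
[0, 1]. A `norm="range"` variant divides by `max v - min v` instead;
`max` is the default because it is the canonical CT normalization. Raw
counts are retained alongside the normalized values.

The combined feature set is the CKSAAP block followed by the CT block:
743 named columns (`AA.gap3` ... `VY.gap3`, then `ct111` ... `ct777`).
Sequences shorter than `max(k + 2, 3)` are rejected, not padded.
Residues outside the 20-letter alphabet (ambiguity codes B/X/Z, rare
J/O/U, gaps, stops) make both descriptors undefined; dataset loading
drops such records with a logged count, single-sequence calls raise.

## Rebalancing

Curated antioxidant datasets are heavily imbalanced (about 1:6 and
worse), which biases a classifier toward the majority class and
depresses sensitivity. Two samplers are implemented, applied to the
training matrix only — the pipeline splits train/test before this phase
so test data can never be resampled:

* **SMOTE.** Synthetic minority rows `x_new = x_i + u (x_nn - x_i)`,
  `u ~ Uniform(0,1)`, with `x_nn` one of the `k = 5` nearest minority
  neighbours of `x_i` (Euclidean metric on the raw feature values,
  which are already frequency-scaled to comparable ranges). Parents are
  drawn uniformly at random per synthetic row. Original rows are
  preserved byte-identically and synthetic rows are flagged
  (`__smote<i>`) in their sample ids. `k = 5` is the de-facto standard
  default. Every synthetic coordinate lies between its two parents'
  coordinates, so synthetic points cannot leave the minority bounding
  box — a property the tests verify against an independent
  brute-force nearest-neighbour oracle.
* **Random undersampling.** Seeded uniform subsampling of the majority
  class without replacement; the minority class is untouched and all
  surviving rows are originals.

Both target a configurable minority:majority ratio (default 1:1, so a
200/1500 training matrix becomes 1500/1500 under SMOTE or 200/200 under
undersampling). Other rebalancers (ADASYN, borderline/SVM SMOTE,
cluster-centroid or NearMiss undersampling, SMOTE+ENN/Tomek cleaning)
are deliberately out of scope; the pipeline's `balance.method: none`
gives the unbalanced baseline.

## MRMD feature selection

Each feature `F_i` of the (rebalanced) training matrix is scored by
relevance plus distance:

* `MR_i = |PCC(F_i, C)|`, the absolute Pearson correlation with the 0/1
  class vector. A zero-variance column has undefined correlation; it is
  scored `MR = 0` (with a warning at the single-vector API level),
  keeping it rankable through its distance term.
* `MD_i = (1/(M-1)) * sum_{k != i} ||F_i - F_k||_2`, the mean Euclidean
  distance between feature columns across samples — a redundancy
  penalty (duplicated columns contribute zero distance to each other).

The score is `MRMD_i = MR_i + MD_i`, sorted descending with a stable
sort (ties keep original column order). Because `MR` is bounded by 1
while raw column distances grow with sample count, feature columns are
min-max scaled to [0, 1] before the distance term by default
(`scale="minmax"`); `scale="none"` reproduces the literal unscaled sum.
Euclidean distance is the only implemented metric.

**Incremental selection** walks the ranking in blocks of `step`
features (the full set is always evaluated last), scoring each prefix
subset by stratified k-fold cross-validated accuracy of a seeded random
forest, and returns the smallest subset attaining the maximal accuracy.
Consequently the chosen accuracy is never below the full-set accuracy
on the same folds. `step = 1` replicates the exhaustive per-feature
walk; the full-scale experiment below uses `step = 10` (75 subset
sizes over 743 features), a grid resolution chosen to keep the
two-arm, five-seed experiment around ten minutes on one CPU. For the
same reason the search forest is deliberately light (30 trees, 3-fold
CV) — it only has to rank subset sizes — while the final model always
uses the 100-tree default.

## Classifier and evaluation

The classifier is a random forest (scikit-learn estimator; 100 trees,
unlimited depth, sqrt(M) candidate features per split, seeded). The
positive-class score of a sample is the **fraction of trees voting
positive** — the forest is used as a voting ensemble, not through
averaged leaf probabilities — and the decision threshold for confusion
counts is 0.5, ties going positive. From confusion counts TP/FP/FN/TN:

    Sn  = TP / (TP + FN)              Sp  = TN / (TN + FP)
    Acc = (TP + TN) / total           F   = 2 TP / (2 TP + FN + FP)
    MCC = (TP·TN - FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Any metric with a vanishing denominator is defined as 0 (the standard
degenerate-confusion convention). The ROC curve plots Sn against
1 - Sp over all vote-fraction thresholds; tied scores cross the
threshold simultaneously, and AUC is the trapezoidal area — provably
equal to the normalized Mann-Whitney U statistic with ties at half
weight, which the tests assert to 1e-10 on random score vectors.
Cross-validation is stratified (per-fold class ratio within one sample
of the global ratio) with a fixed seed; per-fold metrics, their mean
and the pooled confusion are all reported. On a 53-positive /
52-negative test split, counts TP=42 / FN=11 / TN=42 / FP=10 give
Sn 0.792, Sp 0.808, Acc 0.800, F 0.800, MCC 0.600 — the metric engine's
reference case in the acceptance suite.

`group_feature_means` reports class-conditional means and their signed
difference per feature, the view used to ask which triads are enriched
in the positive class (hydrophobic class-1/2 triads, under the planted
signal below).

## Synthetic data

The generator draws sequences i.i.d. per residue: negatives from a
background profile (uniform by default), positives from the same
background with the hydrophobic residues A, G, V, I, L, F, P (CT
classes 1 and 2) up-weighted by a multiplicative `enrichment` factor
and renormalized. This is the simplest mechanism that plants signal in
both descriptor families, and it mirrors the empirical observation that
hydrophobic-class triad content separates antioxidant from
non-antioxidant proteins. Defaults: lengths uniform on 50–300 (so the
`N - 4` and `N - 2` window counts are comfortably positive),
`enrichment = 3`, all positives sharing one enriched profile.
`enrichment = 1` is an exact null — both classes identical — under
which pipeline accuracy sits at chance. An optional `heterogeneity`
parameter (coefficient of variation of a per-sequence Gamma-distributed
signal multiplier `s_i = 1 + (enrichment - 1) g_i`) turns the positive
class into a mixture of strong and near-background sequences for
harder benchmarks; it defaults to 0.

`benchmark_shape_dataset(seed)` is a preset emulating a curated
antioxidant benchmark's shape: 253 positives / 1552 negatives with a
designated 200/1500 training and 53/52 test split, ids disjoint.

What the generator does **not** emulate: motif or domain structure,
positional ordering signal (the process is exchangeable given
composition), homology clusters, length–class correlation, or real
antioxidant biochemistry. Passing tests therefore demonstrate that the
pipeline's machinery — descriptors, rebalancing, ranking, selection,
evaluation — behaves correctly and that rebalancing lifts sensitivity
on compositional signal; they do not certify accuracy on real
proteomes.

## The rebalancing experiment

`antioxseq.experiments.rebalancing_experiment` runs the full pipeline
twice per seed on benchmark-shaped data (enrichment 3): once with SMOTE
to 1:1, once with no rebalancing, everything else identical
(selection `step = 10`, search forest 30 trees / 3-fold CV, final
forest 100 trees). Across seeds 1–5 the SMOTE arm's mean test
sensitivity exceeds the unbalanced baseline's while both arms hold
specificity — the pipeline's central claim, asserted in the acceptance
suite with mean Sn and Sp required above 0.85. The per-sequence test:
even with a homogeneous enriched profile, short sequences carry weak
compositional evidence, so a few test positives are genuinely hard and
the imbalanced baseline misses more of them.

## Numerical and design conventions

* Canonical alphabet order `ACDEFGHIKLMNPQRSTVWY` everywhere an index
  depends on residue identity; CT classes ordered 1..7 as listed.
* Feature-matrix CSV: header mandatory, `sample_id` first column,
  `label` (0/1) last when labeled; floats serialized in repr form so a
  write/read round-trip is exact. Lines starting with `#` are
  provenance stamps and are skipped on read.
* One global pipeline seed fans out as `seed + stage offset`
  (simulate 0, balance 1, select 2, train 3), so any stage can be
  reproduced in isolation.
* Stable sorts and first-argmax tie-breaks throughout (MRMD ranking,
  smallest-subset-at-max-accuracy), making every result deterministic
  given config and seed.
* Model persistence uses joblib; the bundle stores the feature-name
  list and refuses prediction on a matrix lacking those columns.

## Known limitations

* The i.i.d. generator cannot probe order-sensitive failure modes of
  CKSAAP (two sequences with equal composition but different pair
  spacing statistics are rare under it).
* MD dominates MR in the combined MRMD score when sample counts are
  large (distances grow as sqrt(n), correlation stays in [0,1]); this
  follows the score's printed form, and the accuracy-driven subset
  search compensates, but rank positions should not be over-interpreted
  as pure relevance.
* SMOTE interpolation in 743 dimensions concentrates synthetic points
  inside the minority hull; it cannot invent minority modes outside it.
* Single-label binary classification only; no multi-class, no
  probability calibration beyond vote fractions.
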