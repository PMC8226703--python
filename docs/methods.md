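# Methods

## Problem and model

Antifreeze proteins (AFPs) depress the freezing point of body fluids or
inhibit ice recrystallization; recognising them from sequence alone is hard
because AFPs are a structurally heterogeneous class. This package
identifies AFPs from their *functional-domain composition*: each protein is
encoded as a binary vector over InterPro accessions (entry 1 iff the
protein carries the domain), so a collection of annotated proteins becomes
a sparse binary protein × domain matrix with class labels 1 (AFP) and 2
(non-AFP). Proteins with no annotated domain carry no information under
this encoding and are removed at matrix construction (removal counts are
reported per class).

The engine then has three stages.

### 1. mRMR ranking

Domains are ranked by minimum-redundancy-maximum-relevance. With the
already-selected set S, the next feature maximises

    score(f) = I(f, c) − (1/|S|) · Σ_{s∈S} I(f, s)

where c is the class label and I is mutual information. This is the MID
(difference) form with arithmetic-mean redundancy; the redundancy term is
defined as 0 for the first pick, so step 1 selects the most label-relevant
domain. Because every variable here is binary, I is the discrete plug-in
estimator over the 2×2 contingency table, in log base 2 (bits); the base
cancels out of every comparison, so it cannot change a ranking decision.

Numerical choices:

* **Ties** are broken toward the lowest original column index. Scores
  within `1e-9` of the step maximum count as tied, so the outcome does not
  depend on floating-point summation order. Column order itself is
  first-appearance order in the input, which makes the whole construction
  deterministic.
* **Complexity.** Relevance is computed for all N columns in one sparse
  pass; redundancy MI values are materialised lazily — one sparse
  column-co-occurrence product per selected feature — so ranking `top_n`
  features costs O(N · top_n) MI evaluations rather than O(N²). The
  default `top_n = 500` matches the downstream search depth; a full-length
  ranking is available.
* Zero-variance columns have zero MI with everything; they are eligible
  but sort last among equals by index.

### 2. Incremental feature selection (IFS)

From the ranked list F = [f1, f2, …], nested prefixes F1 ⊂ F2 ⊂ … ⊂ F_Kmax
are each evaluated by stratified 10-fold cross-validation of a random
forest trained on the prefix's columns. Per fold, confusion counts
(TP/FP/FN/TN, with AFP as positive) are accumulated; by default counts are
pooled across folds and the four measures evaluated once (per-fold
averaging is available as an option). The four measures are sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy ACC, and the
Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

MCC is the model-selection measure: at ~4.5 % positives, ACC is dominated
by the negative class while MCC stays balanced. Any measure with a zero
denominator is defined as 0 and flagged, which keeps curve comparisons
total (the all-negative predictor scores MCC 0, not NaN). The optimum
subset is the prefix with the highest MCC; ties go to the smallest prefix
(parsimony).

### 3. Random forest

The classifier is a bagged forest of B = 100 trees: each tree grows on a
bootstrap sample of size n drawn with replacement and considers
⌊log₂ m⌋ + 1 candidate features per split for m features — the common
default configuration of the classical implementations. Prediction is
majority vote; an exact 50/50 vote is resolved to the negative class
(documented tie rule; the library default would have favoured the
positive class purely through class ordering). Class imbalance is left
untreated by default, with an optional `class_weight="balanced"` switch.

## Determinism and seeding

One master seed drives everything. Fold assignment is a function of
(row_id, label, seed) only: samples are canonically ordered by
(class, row_id) before the seeded shuffle, and each sample goes to the
fold minimising (per-class load, total load, seeded preference). Training
rows are re-sorted canonically before each forest fit, and each forest's
seed derives from (classifier seed, subset size, fold) via a
`SeedSequence`. Consequently the IFS curve is bit-for-bit invariant to row
permutations of the input matrix, and two runs with the same config are
byte-identical. Stratification is the default because at 4.5 % positives
an unstratified fold can contain no positive at all, leaving SN undefined
for that fold. The hand-rolled fold builder (rather than a library
splitter) is deliberate: it accepts classes with fewer members than folds,
which a 10-fold split of a small positive class requires, and it is what
makes the row-order invariance above exact.

## Synthetic study conditions

The generator emulates the shape of real domain-annotation data — large,
sparse (a few % density), heavily imbalanced — with planted ground truth:

| parameter | default | meaning |
|---|---|---|
| n_pos / n_neg | 200 / 4000 | class sizes (~4.8 % positive) |
| d_inf | 10 | informative domains, Bernoulli(p_pos) in AFPs, Bernoulli(p_neg) otherwise |
| p_pos / p_neg | 0.6 / 0.02 | presence probabilities |
| d_red / flip_prob | 20 / 0.05 | noisy copies of informative columns |
| d_noise / q | 1000 / 0.03 | class-independent noise columns |

Rows that come out all-zero are resampled (not dropped) so the class
counts stay exact and the no-all-zero-row matrix invariant holds; a spec
whose probabilities cannot produce nonzero rows errors out after a bounded
number of attempts. Columns are class-conditionally independent apart from
the planted redundancy — real domain co-occurrence networks are richer, so
passing the planted-truth tests shows the engine recovers this kind of
signal, not that it reproduces real-data performance.

## Problem sizes used by the test suite

* Oracle-equivalence checks run exhaustively at small scale (≤ 60 rows,
  ≤ 13 columns) against naive quadratic re-implementations.
* Planted-truth recovery runs the full default conditions (4,200 × 1,030)
  over 10 seeds with the subset sweep to K_max = 15, which covers the
  planted informative range.
* The permutation null shuffles labels and requires the IFS peak MCC to
  stay below 0.15 over 20 seeds. It runs at 1,000 samples × 60 columns
  with K_max = 50 and 20-tree forests. The sample size was chosen from a
  null-calibration pilot: with far fewer samples the *best chance
  association* among 60 columns by itself approaches the 0.15 bound, so
  a smaller "faster" version would test a different (chance-correlation)
  regime rather than the engine's behaviour under the null.
* The full-data reproduction check consumes the published 420 × 8998 ×
  13,729 matrix, which is not distributed with the package; the test
  states where to place it and otherwise reports the data as unavailable.

## Known limitations

* The plug-in MI estimator is biased upward at very small n; this is
  immaterial for ranking decisions on thousands of samples but is why the
  oracle tests compare against the same plug-in form, not a debiased one.
* Exact reproduction of published full-data numbers is not expected: the
  original fold assignment and forest seeds are unknown, so agreement is
  statistical (peak MCC within a band, optimum size in a range).
* The generator does not simulate domain co-occurrence structure or
  sequence-level effects; redundancy is planted pairwise only.
* `predict` on proteins whose annotations lack every optimum domain
  degenerates to the forest's all-zero-vector vote — biologically, "no
  evidence", operationally, the negative class in practice.
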