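# Methods

## Model and procedure

The classifier is an undersampling voting ensemble for binary text
classification under severe class imbalance. Let the training data hold
*m* minority (positive) and *M* ≫ *m* majority documents.

**Batching.** Every balanced batch contains all *m* minority documents
plus *m* majority documents, so each submodel sees a 50/50 training set
of size 2*m*. Random batching draws one permutation of the majority ids
and slices it into *n* consecutive chunks, making the majority sets
pairwise disjoint by construction; with the default *n* = 20 and
*m* = 246, 4,920 of the 9,251 majority training documents are used and
the rest are deliberately left untouched (the majority class is never
exhausted). Group batching instead builds one batch per topical
community (group tag) that has at least *m* majority training documents,
sampling without replacement within that community only; disjointness is
automatic because communities are disjoint. Group qualification is
counted on training documents (configurable), and group sampling uses a
per-batch seed (`seed + batch_index` over sorted group names) so each
batch is reproducible independent of the others.

**Submodels.** Default family: logistic regression with L2 penalty,
C = 1, and the deterministic lbfgs solver (the family is fixed; these
hyperparameters are the package's own defaults — no tuning is done).
Each submodel records stratified 10-fold CV accuracy and macro F1 on its
batch, then refits on the full batch; the refit model is what votes on
test data. Alternates for the single-model comparison grid: linear,
RBF, degree-3 polynomial and sigmoid SVMs, and a random forest, all as
shipped by scikit-learn with fixed seeds.

**Voting.** For a document with positive-vote fraction *v* ∈ {0, 1/n,
…, 1}, the ensemble predicts positive iff *v* > *p* **strictly**. The
strictness matters at lattice points: 4/5 votes at *p* = 0.8 is
negative. Because the positive set at a higher threshold is a subset of
the positive set at a lower one, the test recall and false-positive
count are provably non-increasing in *p*; the evaluation layer asserts
this on every sweep. *p* = 0 degenerates to a logical OR; a one-submodel
ensemble at any *p* < 1 reproduces the submodel.

**Splitting.** The train/test split is stratified with per-class test
count `round-half-up(test_fraction · n_c)`. This is the unique simple
rounding rule that maps the reference shape (352 positives, 13,216
controls, 70/30) to the published-style structural counts: 0.30·352 =
105.6 → 106 test positives, 0.30·13,216 = 3,964.8 → 3,965 test
controls, total 4,071 test / 9,497 train, 246 training positives and
thus 492-document batches. CV folds are stratified with fold sizes
differing by at most one within each class; each class's surplus folds
are staggered by a rotating offset so overall fold sizes also differ by
at most one (246+246 into 10 folds gives 49–50 per fold, 24–25 per
class).

**Features.** Bag-of-words token counts over the `size` (default 500)
most frequent tokens. Frequency is total token count across documents
(not document frequency); ties break lexicographically so vocabulary
construction is deterministic and invariant to document order. The
vocabulary is fit on training documents only by default, avoiding
test-set leakage; fitting on the full corpus is possible by passing the
corpus of your choice. The built-in tokenizer is lowercase alphabetic
with punctuation/digits as separators, no stop-word removal, no
lemmatization — deterministic and dependency-free; any `str ->
list[str]` callable can replace it.

**Metrics.** Confusion-derived: plain accuracy, balanced accuracy
(mean of per-class recalls — on a class-balanced set it equals plain
accuracy exactly), positive recall, and both F1 conventions. Positive-
class F1 and macro F1 answer different questions on imbalanced data and
are easy to conflate, so every report carries both, explicitly labeled.
Degenerate F1 denominators return 0 (standard convention); balanced
accuracy on a single-class evaluation set raises instead, because that
indicates a malformed evaluation set, not a zero score. Submodel
statistics use the sample SD (n−1); with one submodel the SD is NaN.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_chars` | 100 | drop documents with fewer raw Unicode characters (pre-tokenization) |
| `vocab_size` | 500 | bag-of-words dimension |
| `test_fraction` | 0.30 | stratified test share, round-half-up per class |
| `cv_folds` | 10 | per-batch CV folds |
| `n_batches` | 20 | random balanced batches per ensemble |
| `min_group_size` | minority count | majority training documents a community needs to earn a batch |
| `thresholds` | 0.4–0.9 | voting thresholds swept at prediction time |
| keyword list | 8 phrase variants | collection phrases removed by the scrub filter |

The keyword list ships as an explicit, overridable default
(burnout, burn out, burned out, burning out, burnt out, burn-out,
burnedout, burntout); matching is case-insensitive, word-boundary
anchored, longest-phrase-first, with leftover double spaces collapsed.

## Synthetic corpus generator

Real screening corpora of this kind cannot be redistributed, so the
generator emulates their structure with a unigram mixture whose
assumptions deliberately coincide with the bag-of-words classifier's,
making expected behavior analyzable:

- tokens are synthetic four-letter words with Zipf(1.1) base weights
  over a `vocab_size`-token background (default 2,000);
- a 25-token class-marker block has weight ×`exp(signal_strength)` in
  positive documents;
- each of `n_groups` communities owns a disjoint 8-token marker block
  with weight ×`exp(group_strength)` in its documents. Positive
  documents are assigned a *latent* community whose markers are boosted
  identically, but the tag is not recorded (only control documents carry
  group tags). Without this, the absence of group markers would itself
  be a class signal and the zero-signal null could not sit at chance;
- with probability `keyword_injection_rate` a positive document gets a
  literal keyword phrase inserted at a random word position — a signal
  channel fully removable by the keyword scrub, kept separate from the
  distributional channel so keyword dependence can be manipulated
  independently;
- document character lengths are log-uniform over `doc_length_range`
  (default 100–5,000, mean ≈ 1,250 — comparable to scraped forum
  posts), and every rendered document respects the range.

Default counts are the reference corpus shape: 352 positives, 13,216
controls, 17 communities (≈2.6% prevalence, every community large
enough to qualify for group batching after a 70/30 split).

Canned scenarios: `paper_shape` (full size, moderate signal 1.5,
injection 0.8), and three 1,560-document scenarios isolating one
behavior each — `easy` (signal 4.0, near-separable), `null` (no signal
of any kind; any classifier's expected balanced accuracy is exactly 0.5
because the class-conditional distributions are identical), and
`keyword_only` (signal 0, injection 1.0, so scrubbing removes the
entire class signal). Injection 1.0 in `keyword_only` is the clean
construction: at lower rates uninjected positives are indistinguishable
from controls and cap submodel recall at the injection rate, blurring
the contrast the scenario exists to show.

**What the generator does not emulate:** natural-language syntax and
semantics, topical correlation between classes (e.g. the overlap
between burnout and depression language), bursty token repetition
within documents, label noise, and community-specific document-length
or style differences. Passing tests therefore demonstrate that the
pipeline's mechanics are correct and that it recovers planted unigram
signal — not that any particular performance level transfers to real
text.

## Problem sizes used in tests and the acceptance script

Structural checks (split arithmetic, batch counts, trivial baseline)
run at the full 13,568-document reference shape — they are exact
integer arithmetic and cost seconds. The full pipeline (vectorization,
20 or 17 submodels, sweep) also runs once at full size. Monte-Carlo
checks (signal-strength recovery over the grid {0, 0.5, 1, 2, 4},
null-at-chance, keyword-scrub contrast) use a scaled shape chosen to
keep the same imbalance character at interactive cost: 120 positives /
1,440 controls / 6 communities, 400-token generator vocabulary,
100–600-character documents, ensembles of 5 batches with 5-fold CV, and
a 450-token classifier vocabulary — at least the number of distinct
generated tokens, so injected keyword tokens (which are rare relative
to background tokens) are never truncated out of the vocabulary and the
keyword experiment measures scrubbing, not vocabulary cutoff.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from a
  single master seed; submodel seeds derive as `seed + batch_index`.
  Fixed seeds give bit-identical splits, batches, predictions, and
  serialized artifacts.
- Vocabulary tie-break is lexicographic ascending after descending
  count — platform-independent determinism.
- The undersampled baseline is implemented *as* a one-batch random
  ensemble (same batch construction, same training path), making its
  equivalence to the ensemble's degenerate case structural rather than
  coincidental; the test suite still verifies prediction-level equality
  through the separate voting code path.
- Length filtering counts raw Unicode characters of the original text;
  it is idempotent and applied before any tokenization.
- Serialized ensembles store per-submodel coefficient vectors,
  intercepts, the vocabulary, the batching mode and the default
  threshold; only the logistic family is JSON-serializable.

## Known limitations

- Group batching requires `min_group_size ≥ m`; communities below the
  threshold are silently unused, which can under-represent their topics
  (the random-batching mode has no such gap).
- The CV metrics reported per submodel describe balanced in-batch
  performance and systematically exceed unbalanced test performance;
  they are reported for comparability, not model selection.
- No probability calibration: vote fractions are not posterior
  probabilities, and the threshold sweep reports all thresholds rather
  than selecting one.
- Single-label binary setting only; no oversampling (SMOTE-style) or
  cost-sensitive alternatives are implemented.
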