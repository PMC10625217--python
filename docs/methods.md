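# Methods

## Problem and model

`litscreen` frames guideline-oriented literature screening as binary
classification of bibliographic records. A record contributes three
feature streams: the title text, the abstract text, and the bibliometric
profile of the publishing journal. The model's distinctive component is
*inter-sample* attention: instead of attending over the tokens of one
text, each article's embedding attends over the embeddings of the other
articles in its mini-batch, so the representation of an article encodes
how it differs from its cohort. Class imbalance — guideline-cited
articles are a few percent of candidates — is addressed twice: negatives
are downsampled without replacement to a 3:7 positive:negative ratio, and
the remaining imbalance is handled by the focal loss.

### Corpus construction

A key phrase is an ordered word list with a proximity window: the phrase
matches a token list when its words occur in order with at most
`max_gap = 3` other tokens between each consecutive pair. Tokenization
lowercases, maps every Unicode punctuation character (hyphens included)
to a separator, and splits on whitespace; matching is therefore
case-insensitive and punctuation-blind, the simplest rule consistent
with the canonical worked example (*cervical … pain* across "spine
joint", gap 2). The match reported is the leftmost one, found by
backtracking search — greedy scanning is wrong because the earliest
occurrence of a middle word can strand the rest of the phrase
(`[a, b, b, x, c]` for `(a, b, c)` at gap 1 must match through the second
`b`). Phrases are order-sensitive by design: the default list contains
both *neck pain* and *pain neck* as separate entries.

Deduplication keeps the first occurrence, keying on the record id and
falling back to the normalized title. Records whose journal id does not
resolve in the journal table are dropped. Labels come from a supplied
list of positive ids (articles cited by CPGs or systematic reviews);
unknown positive ids warn rather than fail, since upstream filters may
legitimately have removed them. Downsampling draws
`round(n_pos · (1−f)/f)` negatives uniformly without replacement
(f = 0.3 by default; with 1,005 positives that is exactly 2,345) and
never touches positives. The positive:negative imbalance ratio, where
reported, is always computed from the actual counts.

### Text encoders

The default `toy` backend is a deterministic hash–pool–project encoder:
prepend a reserved classification token, truncate to `max_len` (512)
tokens, hash each token into one of `dim` buckets (blake2b mod dim, a
stable hash — Python's salted `hash()` would break run-to-run
determinism), mean-pool the bucket indicators, and apply a fixed
`dim × dim` Gaussian projection drawn once from the encoder seed.
Default `dim = 64` keeps hash collisions manageable for vocabularies of
a few hundred types while staying desk-scale. Empty text encodes the
classification token alone — defined, not an error.

A `pretrained` backend wraps a biomedical transformer (final-layer
classification-token state, the model's own tokenizer, tail truncation)
behind the same interface; it requires the optional `torch` +
`transformers` extra and is not exercised by the test suite. The
backbone is shared between titles and abstracts; the attention
projections are per-stream.

### Inter-sample attention

For a batch matrix `r` (s×d): `Q = rW^Q`, `K = rW^K`, `V = rW^V` with
square, bias-free projections; `α_i = softmax(q_i Kᵀ)`;
`R_i = α_i V`. There is **no** `1/√d` score scaling by default — the
defining formulation has none — but `scaled_attention: true` enables the
conventional variant (identical when d = 1). Properties maintained and
tested: rows of the weight matrix are non-negative and sum to 1, the
operation is permutation-equivariant in the batch, and each output row
lies in the convex hull of the value rows.

Because each prediction depends on its batch-mates, batch composition is
part of the model's input. Training batches are drawn from a seeded
permutation each epoch. Evaluation batches are formed over the id-sorted
inputs and logged at DEBUG level; this makes predictions deterministic
and invariant to input order, which the ranking contract requires.

### Journal features

Eleven continuous metrics (impact factor for each year 2015–2021 —
treated as seven separate features — CiteScore, SJR, SNIP, H-index) are
z-scored with mean/sd (ddof = 1) learned on the **training split only**,
preventing test leakage. Missing values are imputed with the training
median and flagged (one flag per metric family: IF, CS, SJR, SNIP,
H-index); the citation-report zone is one-hot with an explicit fifth
"unknown" category. Features constant or entirely absent in training
transform to zero and are flagged. The resulting 21-vector passes
through a trainable feed-forward + ReLU layer whose output width
defaults to the input width (configurable).

### Head, loss, training

The fused vector `X_i = concat(R_i, N_i, J_i)` feeds a dense layer to
**two** logits and a softmax. (A square `d̃ × d̃` head cannot produce a
two-class softmax; d̃ → 2 is the only shape consistent with the model's
intent.) The focal loss
`FL(i) = −α̃ (1−p̃_i)^γ log p̃_i` uses γ = 2, α = 0.8 by default —
exposed as configuration, not re-searched here — with probabilities
clamped to `[1e−7, 1 − 1e−7]` and the **mean** over the batch as the
reduction, keeping the learning-rate scale batch-size invariant.

The backbone being frozen, the trainable parameters are the six
attention projections, the journal layer, and the head. Gradients are
derived by hand (softmax-attention backward, ReLU mask, focal-loss
gradient with the γ-term dropped identically at γ = 0) and verified
against central finite differences at 1e−5. The optimizer is Adam
(default; plain SGD available) at learning rate 0.01, batch size 32,
20 epochs — chosen from loss-descent behaviour on the default synthetic
corpus. `epochs = 0` returns the seeded initialization untouched; a
non-finite loss aborts with diagnostics. Checkpoints are single JSON
files (floats round-trip exactly via `repr`), recording the config and
its hash; reloading restores bit-identical predictions.

### Evaluation and screening

Confusion counts at threshold 0.5 and the five standard rates as
percentages; F1 is always the harmonic mean of the report's own
precision and recall. The headline ranking metric is standard ROC AUC
(trapezoid over all thresholds); average precision is reported
alongside as the precision–recall summary. AUC is undefined (reported
as `None`) on single-class labels; empty-denominator rates are 0.
`compare_models` returns per-metric differences in percentage points.
`rank_screen` supports the high-recall triage procedure: lower the
threshold, rank retained articles by descending probability (ties broken
by id), and read from the top. Lowering the threshold never drops a
previously retained article.

The train/test split is stratified 80/20 by default (the 3:7 ratio is
fragile in small runs under purely random splitting); no validation
split or early stopping is used. Ablation variants — T, A, J, TJ, TA,
AJ, FULL — select which feature blocks feed the head.

## Synthetic data

The generator emulates the three inputs (records, positive ids, journal
table) with planted signal:

- every title embeds one of the five default key phrases with 0–3
  fillers between phrase words, inserted last so nothing widens its
  gaps — 100 % of records pass the screen by construction;
- positive articles carry discriminative "methodology vocabulary"
  tokens in the title and, independently, the abstract, each with
  probability `signal_strength` (default 0.9); the token count scales
  with text length. Negatives never use that vocabulary, so the default
  corpus is cleanly separable;
- each journal metric family's log-value has mean shift
  `journal_effect` (default 1.5) standard deviations for positives, with
  sd 1 and cross-family correlation 0.5 via a shared latent — metrics
  co-vary, as real bibliometrics do, without being redundant; zones tilt
  toward 1–2 for positives; cells go missing at `missing_rate` (0.05);
- defaults are 180 positives / 420 negatives (the 3:7 ratio at n = 600),
  vocabulary 500; text is emitted as token sequences, not prose, since
  every consumer tokenizes.

With `signal_strength = 0` and `journal_effect = 0` the label is
independent of everything — the null generator, verified by two-sample
tests. The generator is a pure function of config + seed.

**What passing tests do not show:** the generator does not mimic real
PubMed token statistics, natural-language fluency, the full 1:26
imbalance, shared journals across articles, or label noise (real
"negatives" include uncited but worthy articles). Results on the
synthetic corpus demonstrate that the pipeline learns planted signal of
the assumed structure, not field performance on real literature.

## Problem sizes and numerical choices

The end-to-end study trains on the default 600-article corpus (480
train / 120 test) with the toy encoder at d = 64 for 20 epochs — a few
seconds per run on one CPU — over three seeds, with single-feature
ablations for comparison; the full feature set reaches test ROC AUC
≥ 95 % on every seed and exceeds each single-feature variant.
Full-vs-pairwise-variant differences are within seed noise at this scale
and are reported without a dominance claim. Tolerances: attention
oracles at 1e−10, gradient checks at 1e−5, scaler oracles at 1e−12,
row-stochasticity at 1e−6, z-score idempotence at 1e−9.

## Known limitations

- The numpy trainer is single-threaded and desk-scale; fine-tuning a
  transformer backbone is out of scope.
- Attention context is the batch, so probabilities shift slightly with
  batch size; the id-sorted evaluation batching makes this deterministic
  but does not remove it.
- Journal metrics must be supplied by the user; no bibliometric
  database is scraped.
- Multi-head attention, probability calibration, and positive-unlabeled
  handling of the "negative" class are not implemented.
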