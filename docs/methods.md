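# Methods

## Problem setting

A plant EMR is modeled as three field groups — environment (onset date,
location, field distribution), plant (species, growth stage, affected
part), symptom (severity, main symptoms, detail) — plus a normalized
prescription label. The recommendation task is retrieval: embed a query
record, compare it by cosine against an embedded reference corpus, and
return the top-N *distinct* prescriptions. Counting distinct
prescriptions (rather than reference rows) is a deliberate choice: a
prescription that dominates the reference set would otherwise fill every
slot of the list and make N meaningless. Ties in cosine break toward the
earlier reference row, making ranking fully deterministic.

## Data preparation

Records are NFKC-normalized (this folds full-width characters onto their
half-width forms), whitespace-collapsed, and their prescription names
canonicalized through an alias table keyed on case-folded text.
Duplicates — identical full serialized text *and* prescription — are
dropped conservatively; records without a prescription or without any
symptom text are rejected with the offending record id.

Serialization concatenates the selected field groups in the fixed order
environment → plant → symptom, joining fields with the reserved `[FSEP]`
token that is registered in the tokenizer vocabulary. Keeping empty
fields as empty slots keeps field positions aligned across records and
makes the field-ablation comparisons clean.

Splits are stratified by prescription with largest-remainder rounding
inside each stratum; a stratum smaller than the number of parts goes
entirely to the largest part (preserving rare prescriptions for
training) with a warning. Pairs are all unordered within-split record
pairs, labeled positive iff the prescriptions match; negatives are
down-sampled (seeded, without replacement) to `balance_ratio × n_pos`,
default 1:1. An optional `max_positives` cap down-samples positives
first — the pair universe of even a mid-sized corpus is quadratic, and
a few hundred balanced pairs per epoch are plenty at the corpus sizes
used here (see *Problem sizes*).

## Encoder

The trainable encoder is a small BERT-style stack: token + learned
position embeddings (plus a single shared segment embedding — inputs are
always single sentences), L blocks of multi-head scaled dot-product
attention with padding keys excluded from the softmax, residual
connections, layer normalization, and a GELU feed-forward sublayer.
The attention equations alone do not train stably; the residual/norm/FFN
scaffolding of the architecture family it mirrors is used around them.
The feed-forward hidden width defaults to 2·d rather than the
conventional 4·d — at d = 64 the model is deliberately the smallest
thing that trains well from scratch on one CPU, and the FFN is the
single largest matmul cost. Dropout is omitted: the corpora are
synthetic and fully deterministic training (bit-identical histories
under a fixed seed) is a tested contract of the package.

Five pooling operators are provided: `cls` (last-layer [CLS] row),
`mean` (mask-weighted token average), `first_last_avg` (token average of
(first encoder layer + last layer)/2; "first" is encoder layer 1 by
default, configurable to the embedding layer), `pooler`
(Tanh(dense([CLS]))), and a mask-aware elementwise `max`. All five are
padding-invariant to 1e-6, which is property-tested.

Parameters initialize from a seeded normal(0, 0.02). The whole forward/
backward runs on a small reverse-mode autodiff written on NumPy (no
tensor framework is a dependency); softmax and layer-norm are fused tape
nodes because attention-weight arrays dominate memory traffic, and
backward closures deliberately hold no reference to their own node so
graphs free by reference counting as soon as a batch ends.

### Tokenization and out-of-vocabulary hashing

The synthetic corpora use a whitespace tokenizer with a fitted
vocabulary; `[PAD]`, `[UNK]`, `[CLS]`, `[FSEP]` are reserved. By default
unknown tokens map to `[UNK]`. For open-set evaluation the tokenizer can
instead feature-hash unknown tokens into a block of reserved tail ids
(`oov_buckets`, 64 in the shipped pipeline): identical unseen tokens then
share an id while distinct ones mostly do not, so repeated vocabulary in
unseen-class records still produces correlated embeddings. A single
`[UNK]` id would collapse all unseen-class content onto one symbol and
make open-set transfer unrepresentable for a from-scratch encoder;
pretrained subword encoders get the same effect from their tokenizers,
and they plug into the retrieval stack as a plain `texts → matrix`
callable.

## Training objectives

* **CoSENT** (default): `log(1 + Σ exp(λ(cos⁻ − cos⁺)))` over all
  (positive-pair, negative-pair) cross combinations in a mini-batch,
  computed by a stable log-sum-exp with the implicit `exp(0)` term.
  λ defaults to 20, the established default for this loss. A batch with
  only one label class contributes zero loss and is logged, not raised.
* **SBERT softmax**: cross-entropy over logits `Wᵀ(u, v, |u−v|)` with a
  trainable head used only during training; inference is still cosine.
  Kept as the comparison arm for the training/inference-objective
  mismatch it exemplifies.
* **Supervised SimCSE** (τ default 0.05) is implemented and oracle-tested
  at the function level but is not wired into the pair trainer: it
  consumes anchor/positive/hard-negative triads, which same-prescription
  pair data does not provide — precisely the mismatch that motivates
  CoSENT for this data shape.

Optimization is AdamW (decoupled weight decay 0.01; 1-d parameters —
biases and norm gains — are exempt). The learning rate is 2e-5 when
fine-tuning a pretrained encoder and 1e-3 for the small from-scratch
configuration, which is far from convergence at 2e-5 within 15 epochs.
Batch size 32, 15 epochs, max sequence length 80 tokens with truncation
and zero-padding. Pairs re-shuffle each epoch with seed + epoch; the
best checkpoint is the epoch with the highest held-out Spearman (rank
correlation is scale-free, making it the natural model-selection metric
here), and both best and final checkpoints are kept. Batches drop
trailing all-padding columns before encoding; padding invariance of the
pooled embeddings guarantees this changes nothing, and that invariance
is itself under test.

Undefined correlations (constant cosines or constant labels) are
reported as missing values with a warning, never as zero — a silent zero
would corrupt best-checkpoint selection.

## Synthetic corpora

Each latent disease class owns a disjoint core vocabulary per
signal-carrying field group (20 tokens per class per group) and maps to
one prescription; 50 tokens are shared across classes. Fields draw 6
tokens each; with probability `noise_rate` a core token is replaced by a
shared one; non-signal groups draw entirely from the shared pool. A
bag-of-tokens nearest-neighbour classifier — an oracle with no learned
parts — must reach ≥ 95 % class accuracy at noise 0.1 and degrade toward
chance as noise → 1, which is tested before any encoder claim: the
generator is guaranteed to emit learnable signal. A
many-diseases-one-prescription mode verifies that pair labels follow the
prescription, not the latent disease. Open-set corpora reuse the shared
pool but draw fresh classes and prescription names, so surface style
transfers while labels do not.

What the generator does *not* emulate: natural-language syntax, dialect
and misspelling noise, class imbalance, and correlated fields. Passing
tests therefore demonstrate the correctness and qualitative behaviour of
the machinery — contrastive separation, retrieval transfer, ablation
direction — not performance on real agronomic text.

## Problem sizes

The shipped study runs at: 8 classes × 60 records (noise 0.1), split
8:1:1 into experimental/query/reference, experimental split 7:3 into
training and held-out pair sources, positives capped at 150 before 1:1
balancing (≈ 300 training pairs), held-out capped at 64 positives
(128 pairs), encoder d = 64, 4 heads, 2 layers, 15 epochs. The open-set
corpus is 4 unseen classes × 40 records split 5:5 into query and
reference halves. These sizes are the package's own choice of a
configuration that a single CPU trains in about a minute while leaving
all the qualitative effects measurable; they are far below the scale at
which the production numbers of fine-tuned pretrained encoders arise.

## Numerical and design notes

* Cosine on zero-norm vectors raises; the reference index refuses
  non-unit rows (1e-6) and stores float32 in its archive — loading and
  re-saving round-trips bit-exactly.
* Retrieval is exact exhaustive search; at tens of thousands of rows a
  dot product against the full matrix is cheap and approximate indexing
  would only add failure modes.
* The recommendation-protocol runner serializes queries and references
  with the *same* field-group subset during ablation; a query whose true
  prescription is absent from the reference counts as a miss (the
  open-set protocol depends on honest counting here), and the
  closed/open label is derived from prescription-set overlap with the
  training manifest.
* `run_protocol`, the trainer and the index builders are all pure
  functions of their seeds; byte-identical artifacts across runs are
  asserted by the test suite.

## Known limitations

Whitespace tokenization cannot model subword regularities; the OOV
hashing mitigates, but cannot replace, a pretrained subword vocabulary.
The from-scratch encoder's absolute accuracy saturates on the synthetic
task and says nothing about real-corpus headroom. Training is
single-threaded CPU float64 — adequate at these sizes, not for
fine-tuning large encoders, which should enter through the plug-in
contract instead.
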