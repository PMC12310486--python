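# Methods

`mirlink` predicts which miRNAs repress which mRNAs by fusing two views of
the molecules: what their sequences look like (k-mer embeddings refined by a
CNN–BiLSTM encoder and a mutual-attention layer) and where they sit in the
known interaction network (GraRep node embeddings of the bipartite
miRNA–mRNA graph). A small fully connected ("BP") network fuses both views
into an interaction probability. This note records the model, its
assumptions, the parameters that matter, and the design decisions taken
where the method family leaves choices open.

## Sequence preprocessing

Sequences are normalized to the RNA alphabet (T→U, uppercase, ambiguity
codes rejected — the 4^k vocabulary has no slot for them). mRNAs are
**reversed** end-for-end once at ingestion, so the encoder reads them 3′→5′,
antiparallel to the miRNA, mirroring the geometry of the miRNA:mRNA duplex.
Reversal is character reversal only; complementation is handled at the token
level (below). The same reversed orientation is used for pretraining and for
the classifier, so both stages see identical text.

Both molecules are tokenized into overlapping 6-mers (a length-L sequence
yields L−5 tokens). For pretraining, miRNAs contribute whole-sequence
sentences; mRNAs are first cut into overlapping fragments with
seeded-uniform lengths in [200, 400] nt and a 100 nt overlap between
consecutive fragments (the overlap keeps potential binding sites intact at
fragment boundaries; a trailing remainder shorter than 200 nt merges into
the previous fragment).

## k-mer embedding pretraining

Embeddings are trained with the skip-gram objective — maximize
Σ_g Σ_{c∈context(g)} log P(c|g) over the token corpus — estimated by
negative sampling (5 negatives per pair, unigram^0.75 noise distribution)
rather than the full 4096-way softmax, the standard estimator for this
model family. Character n-gram subwords over the 6-letter tokens (range
3–5, boundary-marked) are composed into each word's input vector by
averaging, FastText-style; a toggle recovers plain skip-gram. k-mers absent
from the corpus keep zero rows so unseen tokens stay inert downstream.

Defaults: dim 64 (matching the downstream encoder width), window 5, 5
epochs with linear learning-rate decay from 0.05, min_count 1, single
worker. The trainer is vectorized numpy and bit-reproducible under a fixed
seed. On the default synthetic corpus (~74k tokens) training takes ~10 s;
the distributional property (tokens sharing contexts end up closer in
cosine than random pairs) saturates well before 5 epochs at this corpus
size, which is why the default is below the 10-epoch convention sometimes
used for larger corpora.

## GraRep node features

The interaction graph is bipartite: nodes are miRNAs and mRNAs, edges are
known interactions, S is the symmetric 0/1 adjacency in sorted-miRNA-then-
sorted-mRNA order. GraRep factorizes log-transformed powers of the
transition matrix A = D⁻¹S. For each step order k = 1..K:

    Γ_j^k = Σ_p A^k[p, j]
    X^k   = max(0, log(A^k / Γ^k + ε) − log β)
    W^k   = U_d Σ_d^{1/2}   from the truncated SVD of X^k

and the node feature is the concatenation W = [W^1 | … | W^K]. The Γ
(column-mass) normalization inside the log follows the original GraRep
semantics; a `use_gamma=False` switch computes the plain log(A^k + ε) − log β
variant instead. Defaults: K = 4, d = 16 (so the node feature is 64-d,
matching the sequence feature width), β = 1/N, ε = 1e−9. The SVD is a
deterministic dense solve with a fixed sign convention (each singular
vector's largest-magnitude entry is positive), so runs are bit-comparable;
at the graph sizes this package targets (10²–10⁴ nodes) dense linear
algebra is exact and fast.

Isolated nodes get all-zero transition rows (logged); nodes absent from the
graph used for embedding (cold start) get zero feature vectors. During
cross-validation the graph is rebuilt per fold **from training-fold positive
edges only**, so test edges never leak into node features; a `full_graph`
switch reproduces the leaky whole-graph alternative for comparison.

## The pair encoder

Per side, token ids are embedded (table initialized from pretraining, then
fine-tuned), convolved (64 filters, kernel 5, same padding, ReLU),
max-pooled over non-overlapping windows of `pool` positions, and run
through a BiLSTM (32 hidden units per direction, standard gate equations,
forward/backward states concatenated to width 64). Hidden and cell states
are multiplied by the position mask at every step, so recurrent state is
exactly zero across padding — important for the backward direction, which
enters the sequence through the padded tail.

Mutual attention then lets the miRNA query the mRNA: per head,
Q = H_mi W_Q, K = H_m W_K, V = H_m W_V, scores = QKᵀ/√d_k, row-softmax over
mRNA positions (padded keys masked to −∞), output = αV, heads concatenated
(4 heads, d_k = 16). In the default mode the mRNA sequence vector is the
pooled encoder output; a bidirectional option adds the transposed-role pass.

### Duplex scoring path

Uninformed cross-attention must discover which k-mer pairs co-occur in
interacting molecules from scratch; at small training sizes that
bootstrap is unreliable, because attention weights are near-uniform over
hundreds of positions and the per-example gradient on any single (k-mer,
k-mer) association is diluted by the thousands of position pairs scored.
The encoder therefore builds Watson–Crick pairing in as an *initialization*
rather than hoping to rediscover it:

- **Antisense tokenization.** mRNA token ids are relabeled through the
  complement permutation of the vocabulary (A↔U, C↔G per position; a
  bijective involution, so no sequence information is lost). Combined with
  the 3′→5′ reversal, the mRNA stream is effectively read as its antisense
  strand: a stretch that would base-pair with the miRNA carries the *same*
  token ids as the miRNA itself.
- **Duplex scores.** A second score path operates on the raw embeddings at
  single-k-mer resolution: S[i,j] = (E_mi W_QE)(E_m W_KE)ᵀ/D, summed along
  the pairing diagonal over `duplex_window` = 2 consecutive positions (an
  ungapped local-alignment scan — one exact 6-mer match occurs by chance
  several times in any long transcript, but two consecutive matches pin
  down a ≥7 nt site). The result is max-reduced over pool×pool tiles onto
  the coarse attention grid and added to every attention head's scores.
- **Similarity initialization.** W_QE = W_KE = c·I at initialization
  (c = `att_eye_scale`), and the embedding table is mean-centered and
  row-normalized at encoder init, so a contiguous complementary site scores
  a predictable several-σ peak above background before any training. Both
  projections and the table remain trainable — on real data the path can
  learn non-canonical pairing (G:U wobble, mismatch tolerance) — and an
  `att_init="glorot"` switch removes the prior entirely.
- **Direct readout.** The strongest duplex score, plus the mean per-query
  best score, are appended to the attended feature vector, and the global
  best feeds the logit directly through a 1-parameter linear head
  (weight 0.5, bias −0.5·`duplex_bias` at init). Training therefore starts
  from the duplex detector's decision boundary and refines it, instead of
  racing a memorization shortcut to find it.

The attention input features are the encoder output concatenated with the
window-averaged raw embeddings (a skip connection: convolution and pooling
mix k-mer identity away, and the skip keeps it available to Q/K/V).

### Fusion and training

Sequence vectors are pooled over time with a masked elementwise max
(`seq_pool="max"`; a detector readout that preserves a localized site
signal which a mean over hundreds of positions would dilute — the mean is
available as an option). The four vectors [seq_mi, seq_m, node_mi, node_m]
are concatenated and passed through one hidden ReLU layer (width 64) to a
sigmoid score (`concat_bp`). Variants: elementwise `add`/`average` fusion
(requires equal widths), `dnn` (three hidden layers), and `no_bp`
(linear + sigmoid, no hidden nonlinearity). Ablations: `noatt` removes the
whole attention block including the duplex path; `lstm` replaces the BiLSTM
with a unidirectional LSTM of the same output width; `nolstm` attends
directly over CNN features.

Training minimizes binary cross-entropy (numerically stable logits form)
with Adam (lr 1e−3, batch 64), dropout 0.2 on sequence vectors and the
hidden layer and 0.25 on node features (node features are the easiest
memorization channel in cross-validation). A stratified 10% of the training
pairs is held out for model selection; training runs at most 10 epochs with
patience 3 on validation loss and returns the best-validation parameters.
Default capacities are 25 miRNA tokens and 800 mRNA tokens (the reversed
stream is truncated at its start, i.e. the 3′ end of the original
transcript is kept, where target sites concentrate); pooling width 4 keeps
the recurrent and attention grids at 200 steps. Sizes were chosen so a full
5-fold cross-validation of the default fixture runs in minutes on one CPU
core; every one of them is config-surfaced.

The whole network runs on a compact reverse-mode autodiff engine over
float32 numpy arrays included in the package (`mirlink.autograd`):
broadcasting arithmetic, batched matmul, softmax, im2col convolution, max
pooling, embedding gather and an argmax-routed max reduction, with
gradients verified against central differences in the test suite.
Everything is single-threaded and deterministic under the configured seeds.

## Evaluation protocol

Balanced design: negatives are sampled uniformly without replacement from
the non-interacting cells of the miRNA×mRNA grid, by default as many as
there are positives. Stratified 5-fold cross-validation; per fold the node
features are rebuilt leak-free (above), the model is retrained (fold index
offsets the model seed), and the held-out fold is scored. Reported metrics:
ACC, F1, MCC, SEN, PPV, TNR from confusion counts at threshold 0.5 (score ≥
threshold counts positive, so a 0.5 tie is a positive call), AUC (rank-based
with half credit for ties) and AUPR (average precision). Zero-denominator
metrics are reported as 0 with a logged flag. The summary rows are the
fold mean and the sample (n−1) standard deviation. ROC points are exported
per fold.

## Synthetic data generator

The generator emulates the *shape* of a curated interaction corpus — 40
miRNAs of 22 nt, 120 mRNAs of 200–800 nt, 600 positive + 600 negative pairs
(a scaled-down version of the thousands-of-pairs datasets used in this
field) — with a mechanistic signal: for every positive pair the reverse
complement of the miRNA seed region (positions 2–8) is written into the
partner mRNA at a random position (positions are redrawn so sites of the
same mRNA never overwrite each other). Negatives are unmodified random
pairs of the same molecules, so an mRNA carrying sites for its own partners
is still a negative for everyone else: the discriminative signal is
pair-specific complementarity, not motif presence. A `noise_rate`
label-flip (default 0 in the API; the evaluation fixture uses 0.05)
emulates annotation noise.

What the generator does **not** emulate: binding thermodynamics, site
accessibility and RNA secondary structure, 3′-UTR positional bias,
conservation, expression context, non-canonical (wobble/mismatch) sites,
and realistic sequence composition (transcripts are i.i.d. uniform). A
model that passes these tests demonstrably recovers a planted
seed-complementarity signal end-to-end through the full pipeline; that is
necessary but not sufficient evidence of performance on real data.

Two quantitative consequences of the design are worth noting. A specific
7-mer occurs in a random transcript by chance at ~L/4^7 per pair (~5% at
L≈500), so even the exact substring oracle is not a perfect classifier on
negatives; together with 5% label flips this caps the attainable AUC on the
default evaluation fixture at ≈0.92 (measured with the motif-presence
oracle). The acceptance bound of 0.85 sits below this ceiling.

## Numerical choices and degenerate inputs

- Fragment coordinates are 0-based half-open; fragment lengths are drawn
  with a seeded generator (one spawn per record, so corpus construction is
  order-stable).
- log guards: ε = 1e−9 inside the GraRep log; zero-mass columns of A^k give
  zero columns in X^k (logged). Negative X entries clip to 0.
- SVD sign convention and tie handling as above; ties in σ keep solver
  order.
- Padding uses a dedicated token id with a zero embedding row that is reset
  after every optimizer step; padded positions are masked out of pooling,
  attention (−∞ scores) and the recurrent state.
- BCE is computed in the logits domain (log1p(exp(−|z|)) form), so saturated
  scores cannot produce non-finite losses.
- Seeds: one global seed drives stage-specific seeds through fixed offsets;
  all stochastic draws go through `numpy.random.Generator`.

## Known limitations

- The duplex-scoring path encodes canonical Watson–Crick pairing as its
  starting point; a run with `att_init="glorot"` (no prior) learns much
  more slowly and, at desk-scale training sizes, may not recover the signal
  at all. This mirrors the gap between alignment-based target scanners and
  purely learned models, and is a deliberate trade-off for reliable
  training at small n.
- The evaluation protocol is transductive for node features: molecules
  absent from the training graph fall back to zero vectors, so predictions
  for entirely novel molecules rely on sequence alone.
- Dense GraRep (matrix powers + dense SVD) is exact but O(N³); beyond ~10⁴
  nodes a sparse/randomized solver would be needed.
- On the synthetic fixture the discriminative signal is a short, local,
  exact site, so the BiLSTM's long-range context contributes little: the
  `nolstm` ablation trails the full model only narrowly (and the two can
  tie within fold noise), while removing the attention block entirely
  (`noatt`) collapses performance to chance. Real transcripts, where site
  context and accessibility matter, are where the recurrent stage is
  expected to earn its keep.
- The skip-gram trainer is single-threaded by design (bit-reproducibility
  over speed); a `workers` field exists in the config for interface
  completeness but values other than 1 are not used.
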