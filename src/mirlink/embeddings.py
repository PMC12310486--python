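"""Skip-gram pretraining of k-mer embeddings over an RNA corpus.

The corpus treats every miRNA as one sentence and every (already reversed)
mRNA fragment as one sentence, with overlapping 6-mers as words. Embeddings
are trained with the skip-gram objective — maximize the probability of the
context k-mers around each center k-mer — estimated with negative sampling,
plus FastText-style character n-gram subwords composed into each word vector
(6-letter words still share informative 3-5-mers, e.g. seed cores).

The trained table (4^k x dim) seeds the downstream encoder's embedding layer.
The trainer is a compact, single-threaded numpy implementation so runs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .sequences import (
    FragmentSet,
    KmerVocabulary,
    Role,
    SequenceRecord,
    build_vocabulary,
    fragment_mrna,
    tokenize_kmers,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentConfig:
    """Sliding-window fragmentation settings for pretraining mRNA sentences."""

    min_len: int = 200
    max_len: int = 400
    overlap: int = 100
    seed: int = 0


@dataclass(frozen=True)
class SkipGramConfig:
    """Skip-gram/negative-sampling hyperparameters.

    dim: embedding width (64 matches the downstream encoder).
    window: context radius in tokens.
    negative: negative samples per (center, context) pair, drawn from the
        unigram^0.75 distribution.
    subword_ngrams: character n-gram range composed into word vectors, or
        None for plain skip-gram.
    """

    dim: int = 64
    window: int = 5
    epochs: int = 5
    negative: int = 5
    min_count: int = 1
    subword_ngrams: tuple[int, int] | None = (3, 5)
    seed: int = 0
    workers: int = 1
    lr: float = 0.05
    lr_min: float = 1e-4
    batch_pairs: int = 4096

    def __post_init__(self):
        if self.dim < 1 or self.window < 1:
            raise ValueError("dim and window must be >= 1")


@dataclass(frozen=True)
class KmerEmbeddingMatrix:
    """Pretrained k-mer embedding table aligned with a full k-mer vocabulary."""

    vocabulary: KmerVocabulary
    weights: np.ndarray  # (4^k, dim)

    def __post_init__(self):
        if self.weights.shape[0] != len(self.vocabulary):
            raise ValueError("row count must equal vocabulary size")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite embedding entries")


def build_corpus(
    records: list[SequenceRecord],
    frag_cfg: FragmentConfig = FragmentConfig(),
    k: int = 6,
) -> list[list[str]]:
    """Token sentences for pretraining.

    miRNAs contribute one whole-sequence sentence each; mRNAs (expected to be
    reversed already) contribute one sentence per overlapping fragment.
    Deterministic given input order and ``frag_cfg.seed``.
    """
    sentences: list[list[str]] = []
    for idx, rec in enumerate(records):
        if len(rec.residues) < k:
            logger.warning("skipping %s: shorter than k=%d", rec.id, k)
            continue
        if rec.role is Role.MIRNA:
            sentences.append(tokenize_kmers(rec.residues, k))
        else:
            rng = np.random.default_rng([frag_cfg.seed, idx])
            fs: FragmentSet = fragment_mrna(
                rec, frag_cfg.min_len, frag_cfg.max_len, frag_cfg.overlap, rng
            )
            for frag in fs.fragments:
                if len(frag.residues) >= k:
                    sentences.append(tokenize_kmers(frag.residues, k))
    return sentences


def _subword_ngrams(word: str, lo: int, hi: int) -> list[str]:
    """Character n-grams of '<word>' (boundary-marked), lengths lo..hi."""
    marked = f"<{word}>"
    grams = []
    for n in range(lo, hi + 1):
        grams.extend(marked[i : i + n] for i in range(len(marked) - n + 1))
    return grams


def train_embeddings(
    corpus: list[list[str]], cfg: SkipGramConfig, k: int = 6
) -> KmerEmbeddingMatrix:
    """Train k-mer embeddings with skip-gram + negative sampling.

    Words absent from the corpus (or below ``min_count``) get zero rows so
    unseen tokens are inert downstream. With subwords enabled, each word's
    input vector is the mean of its own vector and its n-gram vectors
    (context/output vectors are word-only, the usual FastText estimator).
    """
    if not corpus:
        raise ValueError("empty corpus")
    vocab = build_vocabulary(k)
    n_words = len(vocab)
    rng = np.random.default_rng(cfg.seed)

    # --- encode sentences and count
    counts = np.zeros(n_words, dtype=np.int64)
    encoded = []
    for sent in corpus:
        ids = np.array([vocab.index[t] for t in sent], dtype=np.int64)
        encoded.append(ids)
        np.add.at(counts, ids, 1)
    active = counts >= max(1, cfg.min_count)

    # --- composition table: word -> component rows (itself + subword n-grams)
    if cfg.subword_ngrams is not None:
        lo, hi = cfg.subword_ngrams
        gram_index: dict[str, int] = {}
        comp_lists = []
        for w in vocab.tokens:
            comps = [vocab.index[w]]
            for g in _subword_ngrams(w, lo, hi):
                gid = gram_index.setdefault(g, len(gram_index))
                comps.append(n_words + gid)
            comp_lists.append(comps)
        n_comp = len(comp_lists[0])
        if any(len(c) != n_comp for c in comp_lists):
            # ragged only for degenerate k; pad by repeating the word row
            n_comp = max(len(c) for c in comp_lists)
            comp_lists = [c + [c[0]] * (n_comp - len(c)) for c in comp_lists]
        comp = np.array(comp_lists, dtype=np.int64)  # (n_words, n_comp)
        n_rows = n_words + len(gram_index)
    else:
        comp = np.arange(n_words, dtype=np.int64)[:, None]
        n_comp = 1
        n_rows = n_words

    dim = cfg.dim
    w_in = ((rng.random((n_rows, dim), dtype=np.float32) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((n_words, dim), dtype=np.float32)

    # --- (center, context) pairs within the window
    centers_l, contexts_l = [], []
    for ids in encoded:
        keep = active[ids]
        ids = ids[keep]
        n = len(ids)
        for off in range(1, cfg.window + 1):
            if n > off:
                centers_l.append(ids[:-off])
                contexts_l.append(ids[off:])
                centers_l.append(ids[off:])
                contexts_l.append(ids[:-off])
    if not centers_l:
        raise ValueError("corpus has no co-occurring token pairs")
    centers = np.concatenate(centers_l)
    contexts = np.concatenate(contexts_l)

    noise = counts.astype(np.float64) ** 0.75
    noise_p = noise / noise.sum()

    n_pairs = len(centers)
    total_steps = max(1, cfg.epochs * ((n_pairs + cfg.batch_pairs - 1) // cfg.batch_pairs))
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo_i in range(0, n_pairs, cfg.batch_pairs):
            sel = order[lo_i : lo_i + cfg.batch_pairs]
            b = len(sel)
            lr = max(cfg.lr_min, cfg.lr * (1.0 - step / total_steps))
            step += 1
            c_ids = centers[sel]
            ctx_pos = contexts[sel]
            ctx_neg = rng.choice(n_words, size=(b, cfg.negative), p=noise_p)
            ctx = np.concatenate([ctx_pos[:, None], ctx_neg], axis=1)  # (b, 1+neg)
            sign = np.full((b, 1 + cfg.negative), -1.0, dtype=np.float32)
            sign[:, 0] = 1.0

            comp_ids = comp[c_ids]  # (b, n_comp)
            v_in = w_in[comp_ids].mean(axis=1)  # (b, dim)
            v_out = w_out[ctx]  # (b, 1+neg, dim)
            logits = np.einsum("bd,bjd->bj", v_in, v_out)
            # gradient of log sigma(sign * logit)
            g = sign * (1.0 / (1.0 + np.exp(sign * logits)))  # (b, 1+neg)

            grad_in = np.einsum("bj,bjd->bd", g, v_out) * (lr / n_comp)
            grad_out = g[..., None] * v_in[:, None, :] * lr

            flat_rows = comp_ids.ravel()
            mat = sparse.csr_matrix(
                (np.ones(len(flat_rows), dtype=np.float32),
                 flat_rows,
                 np.arange(0, len(flat_rows) + 1, n_comp)),
                shape=(b, n_rows),
            )
            w_in += mat.T @ grad_in
            flat_ctx = ctx.ravel()  # (b*(1+neg),)
            mat_out = sparse.csr_matrix(
                (np.ones(len(flat_ctx), dtype=np.float32),
                 flat_ctx,
                 np.arange(len(flat_ctx) + 1)),
                shape=(len(flat_ctx), n_words),
            )
            w_out += mat_out.T @ grad_out.reshape(len(flat_ctx), dim)

    # --- compose final word vectors; zero out inactive words
    weights = w_in[comp].mean(axis=1)
    weights[~active] = 0.0
    return KmerEmbeddingMatrix(vocabulary=vocab, weights=weights.astype(np.float32))


# ---------------------------------------------------------------------------
# persistence


def save_embeddings(emb: KmerEmbeddingMatrix, path: str | Path) -> None:
    """Save as .npz (binary) or .tsv (portable: token + dim columns)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, weights=emb.weights, k=np.int64(emb.vocabulary.k)
        )
    else:
        with open(path, "w") as fh:
            for tok, row in zip(emb.vocabulary.tokens, emb.weights):
                fh.write(tok + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def load_embeddings(path: str | Path, k: int = 6, dim: int | None = None) -> KmerEmbeddingMatrix:
    """Load an embedding table, validating shape against k (and dim if given)."""
    path = Path(path)
    vocab = build_vocabulary(k)
    if path.suffix == ".npz":
        data = np.load(path)
        if int(data["k"]) != k:
            raise ValueError(f"embedding file has k={int(data['k'])}, expected {k}")
        weights = np.asarray(data["weights"], dtype=np.float32)
    else:
        tokens, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                tokens.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        if tuple(tokens) != vocab.tokens:
            raise ValueError("token order does not match the full k-mer vocabulary")
        weights = np.asarray(rows, dtype=np.float32)
    if weights.shape[0] != len(vocab):
        raise ValueError(f"expected {len(vocab)} rows, found {weights.shape[0]}")
    if dim is not None and weights.shape[1] != dim:
        raise ValueError(f"expected dim={dim}, found {weights.shape[1]}")
    return KmerEmbeddingMatrix(vocabulary=vocab, weights=weights)
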