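"""The miRNA-mRNA pair encoder: embedding -> CNN -> BiLSTM -> mutual attention,
fused with graph node features through a small BP (fully connected) network.

Per side, the k-mer token stream is embedded (table initialized from the
pretrained skip-gram weights, fine-tuned thereafter), convolved with ReLU and
max-pooled to capture local motifs, then run through a BiLSTM for long-range
context. The mutual attention layer lets every miRNA position query the mRNA
positions (Q from the miRNA, K and V from the mRNA, scaled dot product,
row-softmax), which is where pair-specific complementarity is expressed.
Sequence vectors (masked time means) and the two GraRep node vectors are
concatenated and passed through one nonlinear hidden layer to a sigmoid score.

Ablations mirror the design study: ``noatt`` (no attention), ``lstm``
(unidirectional LSTM of the same output width), ``nolstm`` (attention over raw
CNN features). Fusion variants: ``concat_bp`` (default), ``add``, ``average``,
``dnn`` (three hidden layers), ``no_bp`` (linear head only).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .grarep import NodeEmbeddingMatrix, node_vectors
from .sequences import KmerVocabulary, SequenceRecord, build_vocabulary

logger = logging.getLogger(__name__)

ABLATIONS = ("full", "noatt", "lstm", "nolstm")
FUSIONS = ("concat_bp", "add", "average", "dnn", "no_bp")
ATTENTION_MODES = ("mi_queries_m", "bidirectional")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the pair encoder.

    ``mirna_len``/``mrna_len`` are token capacities (pad-or-truncate); the
    mRNA stream is the *reversed* transcript, so truncation keeps its 3' end,
    where target sites concentrate. ``lstm_hidden`` is per direction, so the
    encoder width is 2*lstm_hidden = 64, matching the embedding width.
    """

    k: int = 6
    embed_dim: int = 64
    mirna_len: int = 25
    mrna_len: int = 800
    cnn_filters: int = 64
    cnn_kernel: int = 5
    pool: int = 4
    lstm_hidden: int = 32
    heads: int = 4
    attention_mode: str = "mi_queries_m"
    ablation: str = "full"
    fusion: str = "concat_bp"
    node_dim: int = 64
    fusion_hidden: int = 64
    seq_pool: str = "max"  # time pooling of sequence features: "max" or "mean"
    antisense_tokens: bool = True  # relabel mRNA k-mers by their complement
    attn_residual_embed: bool = True  # skip connection: embeddings into Q/K/V
    duplex_path: bool = True  # single-k-mer-resolution pairing scores in attention
    att_init: str = "eye"  # duplex projections: "eye" (Watson-Crick) or "glorot"
    att_eye_scale: float = 28.0  # initial sharpness of the duplex scores
    duplex_window: int = 2  # consecutive k-mers summed along the pairing diagonal
    duplex_bias: float = 12.0  # score level separating chance matches from sites
    embed_init_rms: float = 0.1  # embedding table is rescaled to this RMS
    node_dropout: float = 0.25  # dropout on node features during training
    dropout: float = 0.2
    lr: float = 1e-3
    epochs: int = 10
    batch: int = 64
    val_fraction: float = 0.1
    patience: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.fusion not in FUSIONS:
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.attention_mode not in ATTENTION_MODES:
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")
        if self.att_dim % self.heads != 0:
            raise ValueError("attention width (2*lstm_hidden) must divide by heads")
        if self.mirna_len < 1 or self.mrna_len < 1:
            raise ValueError("token capacities must be >= 1")
        if self.seq_pool not in ("max", "mean"):
            raise ValueError(f"unknown seq_pool {self.seq_pool!r}")
        if self.att_init not in ("eye", "glorot"):
            raise ValueError(f"unknown att_init {self.att_init!r}")

    @property
    def att_dim(self) -> int:
        """Width of the attention space (= encoder output width)."""
        return 2 * self.lstm_hidden

    @property
    def pad_id(self) -> int:
        return 4**self.k

    def enc_width(self) -> int:
        return self.cnn_filters if self.ablation == "nolstm" else self.att_dim


# ---------------------------------------------------------------------------
# parameters


def init_parameters(
    cfg: ModelConfig, kmer_weights: np.ndarray | None = None
) -> dict[str, Tensor]:
    """Seeded parameter initialization; the embedding table takes the
    pretrained rows (plus a fixed zero pad row) when given."""
    rng = np.random.default_rng(cfg.seed)
    vocab_rows = 4**cfg.k
    if kmer_weights is None:
        table = rng.standard_normal((vocab_rows, cfg.embed_dim)).astype(np.float32)
    else:
        if kmer_weights.shape != (vocab_rows, cfg.embed_dim):
            raise ValueError("pretrained table shape mismatch")
        table = kmer_weights.astype(np.float32).copy()
    # post-process the table: remove the common (anisotropy) direction of the
    # active rows, then normalize each row to a common length so duplex /
    # attention score magnitudes are predictable. Rows of k-mers unseen in
    # pretraining are zero and stay zero (inert downstream).
    active = np.linalg.norm(table, axis=1) > 0
    if active.any():
        table[active] -= table[active].mean(axis=0, keepdims=True)
    norms = np.linalg.norm(table, axis=1, keepdims=True)
    target = cfg.embed_init_rms * np.sqrt(cfg.embed_dim)
    table = np.where(norms > 1e-8, table * (target / np.maximum(norms, 1e-12)), 0.0)
    table = np.vstack([table, np.zeros((1, cfg.embed_dim), dtype=np.float32)])
    params: dict[str, Tensor] = {"embed": ag.parameter(table)}

    kc = cfg.cnn_kernel * cfg.embed_dim
    for side in ("mi", "m"):
        params[f"conv_w_{side}"] = ag.glorot(rng, kc, cfg.cnn_filters)
        params[f"conv_b_{side}"] = ag.parameter(np.zeros(cfg.cnn_filters))
        if cfg.ablation != "nolstm":
            hidden = cfg.att_dim if cfg.ablation == "lstm" else cfg.lstm_hidden
            dirs = ("fw",) if cfg.ablation == "lstm" else ("fw", "bw")
            for d in dirs:
                params[f"lstm_{side}_{d}_Wx"] = ag.glorot(
                    rng, cfg.cnn_filters, 4 * hidden
                )
                params[f"lstm_{side}_{d}_Wh"] = ag.glorot(rng, hidden, 4 * hidden)
                bias = np.zeros(4 * hidden, dtype=np.float32)
                bias[hidden : 2 * hidden] = 1.0  # forget gate bias
                params[f"lstm_{side}_{d}_b"] = ag.parameter(bias)
    if cfg.ablation != "noatt":
        w = cfg.enc_width()
        w_in = w + cfg.embed_dim if cfg.attn_residual_embed else w
        passes = ("",) if cfg.attention_mode == "mi_queries_m" else ("", "2")
        for p in passes:
            params[f"att{p}_WQ"] = ag.glorot(rng, w_in, cfg.att_dim)
            params[f"att{p}_WK"] = ag.glorot(rng, w_in, cfg.att_dim)
            params[f"att{p}_WV"] = ag.glorot(rng, w_in, cfg.att_dim)
            if cfg.duplex_path:
                if cfg.att_init == "eye":
                    # Watson-Crick start: with complement-relabeled mRNA
                    # tokens, a base-paired stretch carries the same k-mer
                    # ids on both sides, so identical projections score
                    # pairing sites high before any training
                    eye = np.eye(cfg.embed_dim, dtype=np.float32) * cfg.att_eye_scale
                    params[f"att{p}_WQE"] = ag.parameter(eye.copy())
                    params[f"att{p}_WKE"] = ag.parameter(eye.copy())
                else:
                    params[f"att{p}_WQE"] = ag.glorot(rng, cfg.embed_dim, cfg.embed_dim)
                    params[f"att{p}_WKE"] = ag.glorot(rng, cfg.embed_dim, cfg.embed_dim)

    if cfg.duplex_path and cfg.ablation != "noatt":
        # direct linear readout of the strongest pairing site: the logit
        # starts at the duplex detector's decision and training refines it
        params["dup_w"] = ag.parameter(np.array([0.5], dtype=np.float32))
        params["dup_b"] = ag.parameter(np.array([-0.5 * cfg.duplex_bias], dtype=np.float32))

    in_dim = _fusion_input_dim(cfg)
    if cfg.fusion == "no_bp":
        params["out_w"] = ag.glorot(rng, in_dim, 1)
        params["out_b"] = ag.parameter(np.zeros(1))
    elif cfg.fusion == "dnn":
        dims = [in_dim, cfg.fusion_hidden, cfg.fusion_hidden, cfg.fusion_hidden]
        for i in range(3):
            params[f"fc{i + 1}_w"] = ag.glorot(rng, dims[i], dims[i + 1])
            params[f"fc{i + 1}_b"] = ag.parameter(np.zeros(dims[i + 1]))
        params["out_w"] = ag.glorot(rng, cfg.fusion_hidden, 1)
        params["out_b"] = ag.parameter(np.zeros(1))
    else:  # concat_bp, add, average
        params["fc1_w"] = ag.glorot(rng, in_dim, cfg.fusion_hidden)
        params["fc1_b"] = ag.parameter(np.zeros(cfg.fusion_hidden))
        params["out_w"] = ag.glorot(rng, cfg.fusion_hidden, 1)
        params["out_b"] = ag.parameter(np.zeros(1))
    return params


def _fusion_input_dim(cfg: ModelConfig) -> int:
    # attended miRNA vector has att_dim; the mRNA sequence vector has enc_width
    if cfg.fusion in ("add", "average"):
        widths = {
            cfg.att_dim if cfg.ablation != "noatt" else cfg.enc_width(),
            cfg.enc_width()
            if cfg.attention_mode != "bidirectional" or cfg.ablation == "noatt"
            else cfg.att_dim,
            cfg.node_dim,
        }
        if len(widths) != 1:
            raise ValueError(
                f"fusion {cfg.fusion!r} needs equal feature widths, got {widths}"
            )
        return widths.pop()
    mi_w = cfg.att_dim if cfg.ablation != "noatt" else cfg.enc_width()
    if cfg.ablation != "noatt" and cfg.duplex_path:
        mi_w += 2  # duplex evidence summary channels
    m_w = (
        cfg.att_dim
        if cfg.ablation != "noatt" and cfg.attention_mode == "bidirectional"
        else cfg.enc_width()
    )
    return mi_w + m_w + 2 * cfg.node_dim


# ---------------------------------------------------------------------------
# forward pieces


def encode_sequence(
    ids: np.ndarray,
    side: str,
    params: dict[str, Tensor],
    cfg: ModelConfig,
    E_full: Tensor | None = None,
) -> tuple[Tensor, np.ndarray, Tensor]:
    """Token ids (B, T) -> encoder features (B, T', width), pooled mask, and
    the window-averaged embeddings (B, T', embed_dim).

    Embedding lookup, same-padding convolution + ReLU, temporal max pooling
    (T' = floor(T/pool)), then the recurrent stage per the ablation setting.
    Padded positions are zeroed after every stage so recurrent state never
    leaks across padding. The window-averaged raw embeddings are returned for
    the attention skip connection: they keep the k-mer identity that the
    convolution/pooling stages mix away.
    """
    mask = (ids != cfg.pad_id).astype(np.float32)  # (B, T)
    E = E_full if E_full is not None else ag.embedding(params["embed"], ids)
    H = ag.conv1d(E, params[f"conv_w_{side}"], params[f"conv_b_{side}"]).relu()
    H = ag.max_pool1d(H, cfg.pool)
    B, Tp, _ = H.shape
    pooled_mask = mask[:, : Tp * cfg.pool].reshape(B, Tp, cfg.pool).max(axis=2)
    mask_t = Tensor(pooled_mask[:, :, None])
    E_pooled = (
        E[:, : Tp * cfg.pool, :].reshape(B, Tp, cfg.pool, cfg.embed_dim).mean(axis=2)
        * mask_t
    )
    H = H * mask_t
    if cfg.ablation == "nolstm":
        return H, pooled_mask, E_pooled
    if cfg.ablation == "lstm":
        H = _lstm_pass(H, pooled_mask, params, f"lstm_{side}_fw", reverse=False)
        return H, pooled_mask, E_pooled
    fw = _lstm_pass(H, pooled_mask, params, f"lstm_{side}_fw", reverse=False)
    bw = _lstm_pass(H, pooled_mask, params, f"lstm_{side}_bw", reverse=True)
    return ag.concat([fw, bw], axis=-1), pooled_mask, E_pooled


def _lstm_pass(
    x: Tensor,
    mask: np.ndarray,
    params: dict[str, Tensor],
    prefix: str,
    reverse: bool,
) -> Tensor:
    """One LSTM direction with the standard gate equations.

    Gate layout in the fused projection is [input, forget, candidate, output].
    Hidden and cell states are multiplied by the position mask each step, so
    state is exactly zero across padded positions (important for the reversed
    direction, which enters the sequence through the padding).
    """
    Wx, Wh, b = params[f"{prefix}_Wx"], params[f"{prefix}_Wh"], params[f"{prefix}_b"]
    B, T, _ = x.shape
    hidden = Wh.shape[0]
    xp = x @ Wx + b  # (B, T, 4H)
    h = Tensor(np.zeros((B, hidden), dtype=np.float32))
    c = Tensor(np.zeros((B, hidden), dtype=np.float32))
    steps: list[Tensor] = [None] * T  # type: ignore[list-item]
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        gates = xp[:, t, :] + h @ Wh
        i = gates[:, :hidden].sigmoid()
        f = gates[:, hidden : 2 * hidden].sigmoid()
        g = gates[:, 2 * hidden : 3 * hidden].tanh()
        o = gates[:, 3 * hidden :].sigmoid()
        m = Tensor(mask[:, t : t + 1])
        c = (f * c + i * g) * m
        h = (o * c.tanh()) * m
        steps[t] = h
    return ag.stack(steps, axis=1)


def duplex_scores(
    E_q: Tensor,
    E_k: Tensor,
    mask_k: np.ndarray,
    pool: int,
    params: dict[str, Tensor],
    cfg: ModelConfig,
    prefix: str = "att",
) -> Tensor:
    """Base-pairing evidence at single-k-mer resolution, on the pooled grid.

    Raw embedding projections are scored position-against-position and summed
    along the pairing diagonal over ``duplex_window`` consecutive k-mers — an
    ungapped local alignment scan. A contiguous Watson-Crick site (which
    after complement relabeling carries the same token ids on both sides)
    then outscores the isolated single-k-mer matches that occur by chance in
    any long transcript. Each pool x pool tile is max-reduced onto the
    coarse attention grid; returns (B, T_q', T_k') scores to be added to
    every attention head.
    """
    B, Tq, D = E_q.shape
    Tk = E_k.shape[1]
    w = min(cfg.duplex_window, Tq, Tk)
    q = E_q @ params[f"{prefix}_WQE"]
    k = E_k @ params[f"{prefix}_WKE"]
    S = (q @ k.transpose(0, 2, 1)) * (1.0 / D)  # (B, Tq, Tk)
    S = S + Tensor(((1.0 - mask_k) * -1e9)[:, None, :])
    if w > 1:
        diag = S[:, : Tq - w + 1, : Tk - w + 1]
        for o in range(1, w):
            diag = diag + S[:, o : Tq - w + 1 + o, o : Tk - w + 1 + o]
        # restore the full grid; trailing positions cannot start a site
        pad_r = Tensor(np.full((B, w - 1, Tk - w + 1), -1e9, dtype=np.float32))
        pad_c = Tensor(np.full((B, Tq, w - 1), -1e9, dtype=np.float32))
        S = ag.concat([ag.concat([diag, pad_r], axis=1), pad_c], axis=2)
    Tq2, Tk2 = Tq // pool, Tk // pool
    S = S[:, : Tq2 * pool, : Tk2 * pool].reshape(B, Tq2, pool, Tk2, pool)
    return ag.amax(ag.amax(S, axis=4), axis=2)


def mutual_attention(
    H_mi: Tensor,
    H_m: Tensor,
    mask_m: np.ndarray,
    params: dict[str, Tensor],
    cfg: ModelConfig,
    prefix: str = "att",
    pair_scores: Tensor | None = None,
) -> tuple[Tensor, Tensor]:
    """Multi-head cross attention: miRNA positions query mRNA positions.

    Per head: Q = H_mi W_Q, K = H_m W_K, V = H_m W_V; scores = QK^T/sqrt(d_k)
    (plus the shared duplex pairing term when given); padded key positions
    get -inf before the row softmax, so every attention row is a distribution
    over real mRNA positions. Heads are concatenated back to
    (B, T_mi, att_dim). Returns (attended features, attention weights).
    """
    B, T_mi, _ = H_mi.shape
    T_m = H_m.shape[1]
    h, dk = cfg.heads, cfg.att_dim // cfg.heads

    def split_heads(x: Tensor, T: int) -> Tensor:
        return x.reshape(B, T, h, dk).transpose(0, 2, 1, 3)  # (B,h,T,dk)

    Q = split_heads(H_mi @ params[f"{prefix}_WQ"], T_mi)
    K = split_heads(H_m @ params[f"{prefix}_WK"], T_m)
    V = split_heads(H_m @ params[f"{prefix}_WV"], T_m)
    scores = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
    if pair_scores is not None:
        scores = scores + pair_scores.reshape(B, 1, T_mi, T_m)
    neg = (1.0 - mask_m)[:, None, None, :] * -1e9  # (B,1,1,T_m)
    alpha = ag.softmax(scores + Tensor(neg), axis=-1)
    out = (alpha @ V).transpose(0, 2, 1, 3).reshape(B, T_mi, cfg.att_dim)
    return out, alpha


def pool_features(
    H: Tensor, mask: np.ndarray | None = None, mode: str = "mean"
) -> Tensor:
    """Pool encoder features over time into one vector per sequence.

    ``mean``: masked arithmetic mean (all-masked rows give zeros).
    ``max``: masked elementwise max over time — a detector readout: it keeps
    the strongest response per feature channel no matter where on the
    sequence it fired, which preserves a localized binding-site signal that
    an average over hundreds of positions would dilute.
    """
    if mode == "max":
        if mask is None:
            B, T, C = H.shape
            return max_pool_time(H, np.ones((H.shape[0], H.shape[1]), np.float32))
        return max_pool_time(H, mask)
    if mask is None:
        return H.mean(axis=H.ndim - 2)
    counts = mask.sum(axis=1, keepdims=True)
    if (counts == 0).any():
        logger.warning("all-masked sequence(s) pooled to zero vectors")
    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0).astype(np.float32)
    s = (H * Tensor(mask[:, :, None])).sum(axis=1)
    return s * Tensor(inv)


def max_pool_time(H: Tensor, mask: np.ndarray) -> Tensor:
    """Masked elementwise max over the time axis of (B, T, C) features."""
    neg = Tensor(((1.0 - mask) * -1e9)[:, :, None])
    return ag.max_pool1d(H + neg, H.shape[1]).reshape(H.shape[0], H.shape[2])


def fuse_and_classify(
    seq_mi: Tensor,
    seq_m: Tensor,
    node_mi: Tensor,
    node_m: Tensor,
    params: dict[str, Tensor],
    cfg: ModelConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Fuse the four feature vectors and return the pre-sigmoid logit (B, 1)."""
    if cfg.fusion in ("add", "average"):
        z = seq_mi + seq_m + node_mi + node_m
        if cfg.fusion == "average":
            z = z * 0.25
    else:
        z = ag.concat([seq_mi, seq_m, node_mi, node_m], axis=-1)
    if cfg.fusion == "no_bp":
        return z @ params["out_w"] + params["out_b"]
    if cfg.fusion == "dnn":
        for i in (1, 2, 3):
            z = (z @ params[f"fc{i}_w"] + params[f"fc{i}_b"]).relu()
            if train and rng is not None:
                z = ag.dropout(z, cfg.dropout, rng, train)
        return z @ params["out_w"] + params["out_b"]
    z = (z @ params["fc1_w"] + params["fc1_b"]).relu()
    if train and rng is not None:
        z = ag.dropout(z, cfg.dropout, rng, train)
    return z @ params["out_w"] + params["out_b"]


def forward_batch(
    params: dict[str, Tensor],
    cfg: ModelConfig,
    mi_ids: np.ndarray,
    m_ids: np.ndarray,
    node_mi: np.ndarray,
    node_m: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Full pair forward pass; returns logits (B, 1)."""
    E_full_mi = ag.embedding(params["embed"], mi_ids)
    E_full_m = ag.embedding(params["embed"], m_ids)
    H_mi, mask_mi, E_mi = encode_sequence(mi_ids, "mi", params, cfg, E_full_mi)
    H_m, mask_m, E_m = encode_sequence(m_ids, "m", params, cfg, E_full_m)
    pool_mode = cfg.seq_pool
    if cfg.ablation == "noatt":
        seq_mi = pool_features(H_mi, mask_mi, pool_mode)
        seq_m = pool_features(H_m, mask_m, pool_mode)
    else:
        if cfg.attn_residual_embed:
            A_mi = ag.concat([H_mi, E_mi], axis=-1)
            A_m = ag.concat([H_m, E_m], axis=-1)
        else:
            A_mi, A_m = H_mi, H_m
        full_mask_mi = (mi_ids != cfg.pad_id).astype(np.float32)
        full_mask_m = (m_ids != cfg.pad_id).astype(np.float32)
        pair = (
            duplex_scores(E_full_mi, E_full_m, full_mask_m, cfg.pool, params, cfg, "att")
            if cfg.duplex_path
            else None
        )
        att_mi, _ = mutual_attention(A_mi, A_m, mask_m, params, cfg, "att", pair)
        seq_mi = pool_features(att_mi, mask_mi, pool_mode)
        duplex_logit = None
        if pair is not None:
            best_all = ag.amax(ag.amax(pair, axis=2), axis=1).reshape(-1, 1)
            duplex_logit = best_all * params["dup_w"] + params["dup_b"]
        if pair is not None and cfg.fusion not in ("add", "average"):
            # duplex evidence summary: strongest site overall and the average
            # per-miRNA-position best pairing score (masked positions of the
            # query side contribute zeros through the pooled-mask product)
            row_best = ag.amax(pair, axis=2)  # (B, T_mi')
            best = ag.amax(row_best, axis=1).reshape(-1, 1)
            counts = np.maximum(mask_mi.sum(axis=1, keepdims=True), 1.0)
            row_mean = (row_best * Tensor(mask_mi)).sum(axis=1, keepdims=True) * Tensor(
                (1.0 / counts).astype(np.float32)
            )
            seq_mi = ag.concat([seq_mi, best, row_mean], axis=-1)
        if cfg.attention_mode == "bidirectional":
            pair2 = (
                duplex_scores(
                    E_full_m, E_full_mi, full_mask_mi, cfg.pool, params, cfg, "att2"
                )
                if cfg.duplex_path
                else None
            )
            att_m, _ = mutual_attention(A_m, A_mi, mask_mi, params, cfg, "att2", pair2)
            seq_m = pool_features(att_m, mask_m, pool_mode)
        else:
            seq_m = pool_features(H_m, mask_m, pool_mode)
    node_mi_t, node_m_t = Tensor(node_mi), Tensor(node_m)
    if train and rng is not None:
        seq_mi = ag.dropout(seq_mi, cfg.dropout, rng, train)
        seq_m = ag.dropout(seq_m, cfg.dropout, rng, train)
        node_mi_t = ag.dropout(node_mi_t, cfg.node_dropout, rng, train)
        node_m_t = ag.dropout(node_m_t, cfg.node_dropout, rng, train)
    logits = fuse_and_classify(
        seq_mi, seq_m, node_mi_t, node_m_t, params, cfg, train, rng
    )
    if cfg.ablation != "noatt" and cfg.duplex_path and duplex_logit is not None:
        logits = logits + duplex_logit
    return logits


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on pre-sigmoid logits."""
    z = logits.data.reshape(-1)
    y = labels.astype(np.float32)
    loss_val = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(np.float32(loss_val.mean()), parents=(logits,))

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accum((g * (s - y) / len(y)).reshape(logits.shape).astype(np.float32))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# datasets of encoded pairs


@dataclass
class PairDataset:
    """Token-encoded, node-featured labeled pairs ready for the encoder."""

    pairs: list[tuple[str, str]]
    mi_ids: np.ndarray  # (n, mirna_len) int64
    m_ids: np.ndarray  # (n, mrna_len) int64
    node_mi: np.ndarray  # (n, node_dim) float32
    node_m: np.ndarray
    labels: np.ndarray  # (n,) int

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(
            [self.pairs[i] for i in idx],
            self.mi_ids[idx],
            self.m_ids[idx],
            self.node_mi[idx],
            self.node_m[idx],
            self.labels[idx],
        )


_COMP = str.maketrans("ACGU", "UGCA")


def complement_permutation(vocab: KmerVocabulary) -> np.ndarray:
    """Vocabulary permutation mapping each k-mer to its positionwise
    Watson-Crick complement (A<->U, C<->G; no reversal).

    Applied to the already-reversed mRNA token stream, this reads the mRNA as
    its antisense strand: a stretch base-paired to the miRNA then carries the
    *same* token ids as the miRNA itself, so cross-attention can recognize
    binding sites as token similarity rather than having to learn every
    (k-mer, complement) association separately. The map is a bijection (an
    involution), so no sequence information is lost.
    """
    perm = np.empty(len(vocab) + 1, dtype=np.int64)
    for i, tok in enumerate(vocab.tokens):
        perm[i] = vocab.index[tok.translate(_COMP)]
    perm[len(vocab)] = len(vocab)  # pad maps to pad
    return perm


def tokens_to_ids(
    residues: str, vocab: KmerVocabulary, capacity: int, pad_id: int
) -> np.ndarray:
    """k-mer token ids, truncated/padded to ``capacity``."""
    k = vocab.k
    n = max(0, len(residues) - k + 1)
    ids = np.full(capacity, pad_id, dtype=np.int64)
    for i in range(min(n, capacity)):
        ids[i] = vocab.index[residues[i : i + k]]
    return ids


def build_pair_dataset(
    pairs: list[tuple[str, str]],
    labels: np.ndarray | list[int],
    records: dict[str, SequenceRecord],
    cfg: ModelConfig,
    node_emb: NodeEmbeddingMatrix | None,
    vocab: KmerVocabulary | None = None,
) -> PairDataset:
    """Encode pairs for the model. mRNA records are expected in *reversed*
    orientation already (the pipeline reverses once, at ingestion)."""
    vocab = vocab or build_vocabulary(cfg.k)
    labels = np.asarray(labels, dtype=np.int64)
    comp = complement_permutation(vocab) if cfg.antisense_tokens else None
    mi_cache: dict[str, np.ndarray] = {}
    m_cache: dict[str, np.ndarray] = {}
    mi_rows, m_rows = [], []
    for mi, m in pairs:
        if mi not in mi_cache:
            mi_cache[mi] = tokens_to_ids(
                records[mi].residues, vocab, cfg.mirna_len, cfg.pad_id
            )
        if m not in m_cache:
            ids = tokens_to_ids(records[m].residues, vocab, cfg.mrna_len, cfg.pad_id)
            m_cache[m] = ids if comp is None else comp[ids]
        mi_rows.append(mi_cache[mi])
        m_rows.append(m_cache[m])
    node_mi = node_vectors(node_emb, [p[0] for p in pairs], cfg.node_dim)
    node_m = node_vectors(node_emb, [p[1] for p in pairs], cfg.node_dim)
    return PairDataset(
        list(pairs), np.stack(mi_rows), np.stack(m_rows), node_mi, node_m, labels
    )


# ---------------------------------------------------------------------------
# training / scoring


def train_model(
    dataset: PairDataset,
    cfg: ModelConfig,
    kmer_weights: np.ndarray | None = None,
) -> tuple[dict[str, Tensor], list[dict]]:
    """Train with Adam on binary cross-entropy; returns the parameters of the
    best validation epoch plus the per-epoch loss history.

    A stratified ``val_fraction`` of the training pairs is held out for model
    selection and early stopping (patience in epochs). Fully deterministic
    under ``cfg.seed`` in single-threaded execution.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    classes = np.unique(dataset.labels)
    if len(classes) < 2:
        raise ValueError("training needs both classes")
    rng = np.random.default_rng(cfg.seed)

    # stratified train/validation split
    val_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(dataset.labels == c)
        members = members[rng.permutation(len(members))]
        n_val = max(1, int(round(cfg.val_fraction * len(members))))
        val_idx.extend(members[:n_val])
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    train_set = dataset.subset(np.flatnonzero(~val_mask))
    val_set = dataset.subset(np.flatnonzero(val_mask))

    params = init_parameters(cfg, kmer_weights)
    opt = Adam(params, lr=cfg.lr)
    pad = cfg.pad_id
    best_val = np.inf
    best_params: dict[str, np.ndarray] = {k: p.data.copy() for k, p in params.items()}
    history: list[dict] = []
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for lo in range(0, len(order), cfg.batch):
            sel = order[lo : lo + cfg.batch]
            opt.zero_grad()
            logits = forward_batch(
                params,
                cfg,
                train_set.mi_ids[sel],
                train_set.m_ids[sel],
                train_set.node_mi[sel],
                train_set.node_m[sel],
                train=True,
                rng=rng,
            )
            loss = bce_with_logits(logits, train_set.labels[sel])
            loss.backward()
            opt.step()
            params["embed"].data[pad] = 0.0  # keep the pad row inert
            losses.append(float(loss.data))
        val_loss = _eval_loss(params, cfg, val_set)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        logger.info(
            "epoch %d: train %.4f val %.4f", epoch, history[-1]["train_loss"], val_loss
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: p.data.copy() for k, p in params.items()}
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    for k, p in params.items():
        p.data = best_params[k]
        p.zero_grad()
    return params, history


def _eval_loss(params: dict[str, Tensor], cfg: ModelConfig, ds: PairDataset) -> float:
    losses, weights = [], []
    for lo in range(0, len(ds), cfg.batch):
        sel = np.arange(lo, min(lo + cfg.batch, len(ds)))
        logits = forward_batch(
            params, cfg, ds.mi_ids[sel], ds.m_ids[sel], ds.node_mi[sel], ds.node_m[sel]
        )
        losses.append(float(bce_with_logits(logits, ds.labels[sel]).data))
        weights.append(len(sel))
    return float(np.average(losses, weights=weights))


def score_pairs(
    params: dict[str, Tensor], cfg: ModelConfig, ds: PairDataset
) -> np.ndarray:
    """Interaction probabilities in [0, 1] for every pair in the dataset."""
    out = np.empty(len(ds), dtype=np.float64)
    for lo in range(0, len(ds), cfg.batch):
        sel = np.arange(lo, min(lo + cfg.batch, len(ds)))
        logits = forward_batch(
            params, cfg, ds.mi_ids[sel], ds.m_ids[sel], ds.node_mi[sel], ds.node_m[sel]
        )
        out[sel] = 1.0 / (1.0 + np.exp(-logits.data.reshape(-1)))
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    path: str | Path, params: dict[str, Tensor], cfg: ModelConfig
) -> None:
    path = Path(path)
    arrays = {k: p.data for k, p in params.items()}
    np.savez_compressed(path, __config__=json.dumps(asdict(cfg)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, Tensor], ModelConfig]:
    data = np.load(Path(path), allow_pickle=False)
    cfg = ModelConfig(**json.loads(str(data["__config__"])))
    params = {
        k: ag.parameter(data[k]) for k in data.files if k != "__config__"
    }
    return params, cfg
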