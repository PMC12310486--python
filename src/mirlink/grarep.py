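"""GraRep node embedding of the bipartite miRNA-mRNA interaction graph.

GraRep factorizes log-transformed powers of the random-walk transition matrix
A = D^-1 S. For each step order k = 1..K it forms a positive log-probability
matrix X^k from A^k, takes its truncated SVD, and keeps W^k = U_d Σ_d^{1/2};
the final node feature is the concatenation [W^1 | ... | W^K], so low orders
capture direct interaction partners and higher orders capture multi-step
(miRNA -> mRNA -> miRNA ...) neighborhood structure.

The bipartite graph here is small enough (thousands of nodes) that dense
linear algebra is exact and deterministic; no stochastic solver is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequences import Role

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionGraph:
    """Bipartite miRNA-mRNA graph with a symmetric 0/1 adjacency matrix.

    Node order is all miRNAs (sorted) followed by all mRNAs (sorted).
    """

    node_ids: tuple[str, ...]
    roles: tuple[Role, ...]
    edges: frozenset[tuple[str, str]]  # (miRNA id, mRNA id)
    S: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def node_index(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.node_ids)}


@dataclass(frozen=True)
class GraRepConfig:
    """K: maximum transition step; d: per-step dimension; beta: log-shift
    factor (None means the standard 1/N); eps: numeric guard inside the log."""

    K: int = 4
    d: int = 16
    beta: float | None = None
    eps: float = 1e-9
    use_gamma: bool = True  # divide A^k by its column sums inside the log

    def __post_init__(self):
        if self.K < 1 or self.d < 1:
            raise ValueError("K and d must be >= 1")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass(frozen=True)
class NodeEmbeddingMatrix:
    """GraRep output W (N x K*d) in graph node order, with per-step blocks."""

    node_ids: tuple[str, ...]
    roles: tuple[Role, ...]
    W: np.ndarray
    K: int
    d: int

    def __post_init__(self):
        if self.W.shape != (len(self.node_ids), self.K * self.d):
            raise ValueError("W must be (N, K*d)")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite embedding entries")

    def block(self, k: int) -> np.ndarray:
        """The k-th step representation W^k (1-based k)."""
        return self.W[:, (k - 1) * self.d : k * self.d]

    def lookup(self, dim_check: int | None = None) -> dict[str, np.ndarray]:
        return {nid: self.W[i] for i, nid in enumerate(self.node_ids)}


def build_graph(pairs: list[tuple[str, str]]) -> InteractionGraph:
    """Build the bipartite graph from (miRNA id, mRNA id) pairs.

    Duplicate pairs collapse to one edge. An id appearing on both sides
    would make a node's role ambiguous and is rejected.
    """
    if not pairs:
        raise ValueError("no pairs given")
    mirnas = {p[0] for p in pairs}
    mrnas = {p[1] for p in pairs}
    clash = mirnas & mrnas
    if clash:
        raise ValueError(f"ids used as both miRNA and mRNA: {sorted(clash)}")
    node_ids = tuple(sorted(mirnas)) + tuple(sorted(mrnas))
    roles = (Role.MIRNA,) * len(mirnas) + (Role.MRNA,) * len(mrnas)
    index = {nid: i for i, nid in enumerate(node_ids)}
    edges = frozenset(pairs)
    n = len(node_ids)
    S = np.zeros((n, n), dtype=np.float64)
    for mi, m in edges:
        i, j = index[mi], index[m]
        S[i, j] = 1.0
        S[j, i] = 1.0
    return InteractionGraph(node_ids=node_ids, roles=roles, edges=edges, S=S)


def transition_matrix(graph: InteractionGraph) -> np.ndarray:
    """Row-normalized adjacency A = D^-1 S; isolated nodes keep zero rows."""
    deg = graph.S.sum(axis=1)
    isolated = deg == 0
    if isolated.any():
        logger.warning("%d isolated node(s): all-zero transition rows", isolated.sum())
    safe = np.where(isolated, 1.0, deg)
    return graph.S / safe[:, None]


def kstep_log_matrix(A: np.ndarray, k: int, cfg: GraRepConfig) -> np.ndarray:
    """Positive log-probability matrix X^k from the k-step transitions.

    X^k[i,j] = log(A^k[i,j] / Γ_j^k + eps) - log(beta), where Γ_j^k is the
    column sum of A^k, then negative entries are clipped to 0. With
    ``use_gamma=False`` the raw A^k is logged instead of the Γ-normalized one.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Ak = np.linalg.matrix_power(A, k)
    beta = cfg.beta if cfg.beta is not None else 1.0 / A.shape[0]
    if cfg.use_gamma:
        gamma = Ak.sum(axis=0)
        dead = gamma == 0
        if dead.any():
            logger.warning("%d zero-mass column(s) in A^%d", dead.sum(), k)
        ratio = np.divide(Ak, np.where(dead, 1.0, gamma)[None, :])
        ratio[:, dead] = 0.0
    else:
        ratio = Ak
    X = np.log(ratio + cfg.eps) - np.log(beta)
    np.maximum(X, 0.0, out=X)
    return X


def kstep_representation(Xk: np.ndarray, d: int) -> np.ndarray:
    """W^k = U_d Σ_d^{1/2} from the SVD of X^k, with a deterministic sign.

    Each singular vector is flipped so its largest-magnitude entry is
    positive; ties in σ keep the solver's original ordering.
    """
    if not np.all(np.isfinite(Xk)):
        raise ValueError("non-finite entries in X^k")
    if d > min(Xk.shape):
        raise ValueError(f"d={d} exceeds matrix rank bound {min(Xk.shape)}")
    U, s, _ = np.linalg.svd(Xk, full_matrices=False)
    Ud = U[:, :d].copy()
    sd = s[:d]
    for j in range(d):
        col = Ud[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            Ud[:, j] = -col
    return Ud * np.sqrt(sd)[None, :]


def grarep_embed(graph: InteractionGraph, cfg: GraRepConfig = GraRepConfig()) -> NodeEmbeddingMatrix:
    """Full GraRep: concatenate the K per-step representations, (N, K*d)."""
    A = transition_matrix(graph)
    blocks = [
        kstep_representation(kstep_log_matrix(A, k, cfg), cfg.d)
        for k in range(1, cfg.K + 1)
    ]
    W = np.concatenate(blocks, axis=1)
    return NodeEmbeddingMatrix(
        node_ids=graph.node_ids, roles=graph.roles, W=W, K=cfg.K, d=cfg.d
    )


def node_vectors(
    emb: NodeEmbeddingMatrix | None, ids: list[str], dim: int
) -> np.ndarray:
    """Per-id embedding rows with a zero-vector fallback for cold-start nodes
    absent from the (training) graph."""
    out = np.zeros((len(ids), dim), dtype=np.float32)
    if emb is None:
        return out
    table = emb.lookup()
    missing = 0
    for i, nid in enumerate(ids):
        vec = table.get(nid)
        if vec is None:
            missing += 1
        else:
            out[i] = vec
    if missing:
        logger.warning("%d node(s) missing from the graph: zero vectors", missing)
    return out


# ---------------------------------------------------------------------------
# TSV plumbing


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            pairs.append((parts[0], parts[1]))
    return pairs


def write_embedding_tsv(emb: NodeEmbeddingMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for nid, role, row in zip(emb.node_ids, emb.roles, emb.W):
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{nid}\t{role.value}\t{vals}\n")
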