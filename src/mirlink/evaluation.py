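"""Negative sampling, stratified cross-validation and the metric suite.

The evaluation protocol mirrors the standard bipartite link-prediction setup:
validated interactions are positives, an equal number of uniformly sampled
non-interacting pairs are negatives, and stratified 5-fold cross-validation
reports ACC, F1, AUC, AUPR, MCC, SEN (recall), PPV (precision) and TNR
(specificity) per fold with mean and sample standard deviation.

To keep node features leak-free, the GraRep graph inside ``cross_validate``
is rebuilt from each training fold's positive edges only, so test edges never
inform the embedding (a ``full_graph`` switch reproduces the leaky
whole-graph alternative).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .grarep import GraRepConfig, build_graph, grarep_embed
from .model import (
    ModelConfig,
    build_pair_dataset,
    score_pairs,
    train_model,
)
from .sequences import Role, SequenceRecord, build_vocabulary, reverse_orientation

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "F1", "AUC", "AUPR", "MCC", "SEN", "PPV", "TNR")


@dataclass(frozen=True)
class LabeledPairSet:
    """Unique (miRNA id, mRNA id) keys with 0/1 labels."""

    pairs: tuple[tuple[str, str], ...]
    labels: tuple[int, ...]

    def __post_init__(self):
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must align")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate (miRNA, mRNA) keys")

    def __len__(self) -> int:
        return len(self.pairs)

    def positives(self) -> list[tuple[str, str]]:
        return [p for p, y in zip(self.pairs, self.labels) if y == 1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=np.int64)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """Per-fold metric dicts plus their mean and sample std rows."""

    folds: list[dict[str, float]]
    mean: dict[str, float]
    std: dict[str, float]
    roc_points: list[np.ndarray] = field(default_factory=list)  # (n,2) fpr/tpr
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "folds": self.folds,
            "mean": self.mean,
            "std": self.std,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def sample_negatives(
    positives: list[tuple[str, str]] | set[tuple[str, str]],
    n: int | None = None,
    seed: int = 0,
    mirna_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Uniform sample (without replacement) of non-interacting pairs.

    The candidate universe is the full miRNA x mRNA grid (ids taken from the
    positives unless given explicitly) minus the positive pairs. Default n
    equals the number of positives (balanced design).
    """
    positives = set(positives)
    mirnas = sorted(mirna_ids if mirna_ids is not None else {p[0] for p in positives})
    mrnas = sorted(mrna_ids if mrna_ids is not None else {p[1] for p in positives})
    n = len(positives) if n is None else n
    total = len(mirnas) * len(mrnas)
    pos_flat = {
        mi_i * len(mrnas) + m_i
        for mi_i, mi in enumerate(mirnas)
        for m_i, m in enumerate(mrnas)
        if (mi, m) in positives
    }
    available = total - len(pos_flat)
    if n > available:
        raise ValueError(f"requested {n} negatives but only {available} available")
    candidates = np.setdiff1d(
        np.arange(total, dtype=np.int64), np.fromiter(pos_flat, dtype=np.int64)
    )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    return [(mirnas[i // len(mrnas)], mrnas[i % len(mrnas)]) for i in chosen]


def kfold_split(
    dataset: LabeledPairSet, folds: int = 5, seed: int = 0
) -> list[tuple[LabeledPairSet, LabeledPairSet]]:
    """Stratified-by-label partition into disjoint, exhaustive test folds."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = dataset.label_array()
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        out.append((_subset(dataset, train_idx), _subset(dataset, test_idx)))
    return out


def _subset(ds: LabeledPairSet, idx: np.ndarray) -> LabeledPairSet:
    return LabeledPairSet(
        tuple(ds.pairs[i] for i in idx), tuple(ds.labels[i] for i in idx)
    )


def confusion(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold scores (>= counts as positive, so a 0.5 tie is positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) == 0:
        raise ValueError("empty input")
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Thresholded metrics from confusion counts.

    ACC = (TP+TN)/total, SEN = TP/(TP+FN), PPV = TP/(TP+FP),
    TNR = TN/(TN+FP), F1 = harmonic mean of PPV and SEN, and
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any zero denominator yields 0 (logged).
    """
    if c.total == 0:
        raise ValueError("no counts")
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    acc = (tp + tn) / c.total
    sen = _safe_div(tp, tp + fn, "SEN")
    ppv = _safe_div(tp, tp + fp, "PPV")
    tnr = _safe_div(tn, tn + fp, "TNR")
    f1 = _safe_div(2 * ppv * sen, ppv + sen, "F1")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    return {"ACC": acc, "F1": f1, "MCC": mcc, "SEN": sen, "PPV": ppv, "TNR": tnr}


def auc_aupr(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Rank-based AUC (ties at half credit) and average-precision AUPR."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUC/AUPR")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def fold_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    m = compute_metrics(confusion(scores, labels))
    m["AUC"], m["AUPR"] = auc_aupr(scores, labels)
    return {k: m[k] for k in METRIC_NAMES}


def _summarize(folds: list[dict[str, float]]) -> tuple[dict, dict]:
    mean = {
        k: float(np.mean([f[k] for f in folds])) for k in METRIC_NAMES
    }
    std = {
        k: float(np.std([f[k] for f in folds], ddof=1)) for k in METRIC_NAMES
    }
    return mean, std


def cross_validate(
    dataset: LabeledPairSet,
    records: list[SequenceRecord],
    model_cfg: ModelConfig,
    grarep_cfg: GraRepConfig | None = None,
    kmer_weights: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    full_graph: bool = False,
) -> MetricReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold: GraRep node features from the training positives (unless
    ``full_graph``), model trained on the training fold, test fold scored.
    ``records`` are natural-orientation sequences; mRNAs are reversed here,
    once, before encoding.
    """
    grarep_cfg = grarep_cfg or GraRepConfig()
    vocab = build_vocabulary(model_cfg.k)
    by_id = {
        r.id: (reverse_orientation(r) if r.role is Role.MRNA else r) for r in records
    }
    full_positives = dataset.positives()
    report = MetricReport(folds=[], mean={}, std={})
    for i, (train, test) in enumerate(kfold_split(dataset, folds, seed)):
        edges = full_positives if full_graph else train.positives()
        node_emb = grarep_embed(build_graph(edges), grarep_cfg)
        fold_cfg = ModelConfig(
            **{**_cfg_dict(model_cfg), "seed": model_cfg.seed + i}
        )
        train_ds = build_pair_dataset(
            list(train.pairs), train.label_array(), by_id, fold_cfg, node_emb, vocab
        )
        test_ds = build_pair_dataset(
            list(test.pairs), test.label_array(), by_id, fold_cfg, node_emb, vocab
        )
        params, _hist = train_model(train_ds, fold_cfg, kmer_weights)
        scores = score_pairs(params, fold_cfg, test_ds)
        labels = test.label_array()
        report.folds.append(fold_metrics(scores, labels))
        fpr, tpr, _ = roc_curve(labels, scores)
        report.roc_points.append(np.column_stack([fpr, tpr]))
        report.fold_scores.append((scores, labels))
        logger.info(
            "fold %d: AUC %.4f ACC %.4f", i, report.folds[-1]["AUC"],
            report.folds[-1]["ACC"],
        )
    report.mean, report.std = _summarize(report.folds)
    return report


def _cfg_dict(cfg: ModelConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def write_scores_tsv(
    path: str | Path,
    pairs: list[tuple[str, str]],
    scores: np.ndarray,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
) -> None:
    with open(path, "w") as fh:
        for i, (mi, m) in enumerate(pairs):
            label = int(scores[i] >= threshold)
            truth = "" if labels is None else f"\t{int(labels[i])}"
            fh.write(f"{mi}\t{m}\t{scores[i]:.6f}\t{label}{truth}\n")


def write_roc_csv(report: MetricReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fold,fpr,tpr\n")
        for i, pts in enumerate(report.roc_points):
            for fpr, tpr in pts:
                fh.write(f"{i},{fpr:.6f},{tpr:.6f}\n")
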