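"""Classification and virtual-screening statistics.

ACC, MCC, precision, recall and F1 are computed from thresholded confusion
counts (probability >= threshold is positive, default 0.5; any zero
denominator yields 0). ROC AUC is the rank-based Mann–Whitney statistic
with midrank tie handling. The enrichment factor

    EF_gamma = (NTB_gamma / NTB_total) * (1 / gamma)

compares the active rate among the top ceil(gamma*N) ranked compounds to
the overall active rate; it is bounded by 1/gamma. Low-similarity test-set
construction removes test molecules whose maximum ECFP4 Tanimoto to any
training molecule exceeds a threshold (default 0.85).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .chem_data import CompoundRecord
from .featurization import ecfp4_fingerprint
from rdkit import DataStructs


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    mcc: float
    precision: float
    recall: float
    f1: float
    auc: float
    counts: ConfusionCounts
    threshold: float

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "mcc": self.mcc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "threshold": self.threshold,
        }


@dataclass
class ScreeningResult:
    """Compounds ranked by predicted probability, with AUC and EF values."""

    ranked_ids: list[str]
    scores: np.ndarray  # descending, aligned with ranked_ids
    labels: np.ndarray  # aligned with ranked_ids
    ntb_total: int
    ef: dict[float, float]
    auc: float


def confusion(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts; a probability exactly at the threshold is positive."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def _check_counts(c: ConfusionCounts) -> None:
    if c.total == 0:
        raise ValueError("empty confusion counts")


def acc(c: ConfusionCounts) -> float:
    _check_counts(c)
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    _check_counts(c)
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    _check_counts(c)
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def f1(c: ConfusionCounts) -> float:
    _check_counts(c)
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 when any marginal is empty."""
    _check_counts(c)
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann–Whitney AUC with midrank tie handling."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(s)  # midranks
    rank_sum_pos = ranks[y == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def metrics_report(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    c = confusion(labels, probabilities, threshold)
    y = np.asarray(labels)
    both_classes = 0 < int(np.sum(y == 1)) < len(y)
    return MetricsReport(
        acc=acc(c),
        mcc=mcc(c),
        precision=precision(c),
        recall=recall(c),
        f1=f1(c),
        auc=roc_auc(labels, probabilities) if both_classes else float("nan"),
        counts=c,
        threshold=threshold,
    )


def enrichment_factor(
    labels: Sequence[int], scores: Sequence[float], gamma: float
) -> float:
    """EF_gamma over the top ceil(gamma*N) by score, ties in stable input order."""
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    ntb_total = int(np.sum(y == 1))
    if ntb_total == 0:
        raise ValueError("no actives")
    n_top = math.ceil(gamma * len(y))
    order = np.argsort(-s, kind="stable")
    ntb_gamma = int(np.sum(y[order[:n_top]] == 1))
    return (ntb_gamma / ntb_total) / gamma


def low_similarity_subset(
    test_records: Sequence[CompoundRecord],
    train_records: Sequence[CompoundRecord],
    threshold: float = 0.85,
) -> list[CompoundRecord]:
    """Test records whose max Tanimoto to the training set is <= threshold."""
    if not train_records:
        raise ValueError("empty training set")
    train_fps = [ecfp4_fingerprint(r.smiles) for r in train_records]
    kept = []
    for rec in test_records:
        fp = ecfp4_fingerprint(rec.smiles)
        sims = DataStructs.BulkTanimotoSimilarity(fp, train_fps)
        if max(sims) <= threshold:
            kept.append(rec)
    return kept


DEFAULT_GAMMAS = (0.01, 0.02, 0.05, 0.10)


def screen(
    model,
    records: Sequence[CompoundRecord],
    gammas: Sequence[float] = DEFAULT_GAMMAS,
) -> ScreeningResult:
    """Rank by predicted probability (descending) and report EF/AUC.

    ``model`` is anything with ``predict_proba(records)`` — a single trained
    network or an averaging ensemble.
    """
    y = np.asarray([r.label for r in records], dtype=np.float64)
    if np.any(np.isnan(y)):
        raise ValueError("screening records must carry activity labels")
    scores = np.asarray(model.predict_proba(records), dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    ids = [
        records[i].id if records[i].id is not None else str(i) for i in order
    ]
    ef = {g: enrichment_factor(y, scores, g) for g in gammas}
    return ScreeningResult(
        ranked_ids=ids,
        scores=scores[order],
        labels=y[order].astype(int),
        ntb_total=int(np.sum(y == 1)),
        ef=ef,
        auc=roc_auc(y.astype(int), scores),
    )
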