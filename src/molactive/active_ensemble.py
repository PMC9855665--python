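"""Pool-based active learning with uncertainty sampling, and ensembling.

The trainer starts from a small seeded labeled set (default 5% of the
training pool, stratified by class), then repeatedly: trains a fresh
classifier on the labeled set, scores the unlabeled pool by uncertainty
1 - max_i P(y_i|x), moves the most uncertain batch into the labeled set per
a geometric batch schedule (denser early, sparser late), and records the
iteration's model. A passive baseline draws the same batch sizes uniformly
at random. The per-iteration models then serve as base learners for an
averaging ensemble whose size is chosen on validation accuracy over
suffixes ("the last N iterations").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem_data import CompoundRecord
from .dmpnn_model import DMPNNConfig, TrainedModel, train, predict_proba
from . import evaluation


@dataclass(frozen=True)
class QuerySchedule:
    initial_fraction: float
    batch_sizes: tuple[int, ...]
    growth: float

    def __post_init__(self) -> None:
        if not (0 < self.initial_fraction < 1):
            raise ValueError("initial_fraction must be in (0, 1)")
        if any(b <= 0 for b in self.batch_sizes):
            raise ValueError("batch sizes must be positive")
        body = self.batch_sizes[:-1]  # final batch may be clipped smaller
        if any(b2 < b1 for b1, b2 in zip(body, body[1:])):
            raise ValueError("batch sizes must be non-decreasing (final batch excepted)")


@dataclass
class PoolState:
    """Trajectory of one active/passive learning run."""

    labeled: list[int]
    unlabeled: list[int]
    iteration: int = 0
    models: list[TrainedModel] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)


@dataclass
class EnsembleModel:
    """Ordered base learners combined by averaging predicted probabilities."""

    members: list[TrainedModel]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_proba(self, records: Sequence[CompoundRecord]) -> np.ndarray:
        return ensemble_predict(self, records)


def uncertainty_score(class_probabilities: np.ndarray) -> float:
    """1 - max_i P(y_i|x); in [0, 0.5] for binary problems."""
    p = np.asarray(class_probabilities, dtype=np.float64)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("malformed probability vector")
    return float(1.0 - p.max())


def select_batch(
    probabilities: np.ndarray, unlabeled: Sequence[int], k: int
) -> list[int]:
    """The k unlabeled indices with highest uncertainty, stable under ties.

    ``probabilities`` are the model's positive-class probabilities aligned
    with ``unlabeled``.
    """
    if k > len(unlabeled):
        raise ValueError(f"k={k} exceeds pool size {len(unlabeled)}")
    probs = np.asarray(probabilities, dtype=np.float64)
    unc = 1.0 - np.maximum(probs, 1.0 - probs)
    # stable sort descending on uncertainty -> ties broken by pool position
    order = np.argsort(-unc, kind="stable")[:k]
    return [unlabeled[i] for i in order]


def make_schedule(
    pool_size: int,
    initial_fraction: float = 0.05,
    first_batch_fraction: float = 0.05,
    growth: float = 1.5,
) -> QuerySchedule:
    """Geometric query schedule b_j = round(first_batch_fraction·pool·growth^j).

    Rounding is half-up; the sequence is truncated and the final batch
    clipped so the batches exhaust ``pool_size`` exactly. ``pool_size`` is
    the unlabeled pool the batches must consume, i.e. the training pool
    minus the initial labeled draw.
    """
    if pool_size <= 0:
        raise ValueError("empty pool")
    if not (0 < first_batch_fraction < 1) or growth < 1:
        raise ValueError("first_batch_fraction in (0,1) and growth >= 1 required")
    batches: list[int] = []
    remaining = pool_size
    j = 0
    while remaining > 0:
        b = int(math.floor(first_batch_fraction * pool_size * growth**j + 0.5))
        b = max(1, min(b, remaining))
        batches.append(b)
        remaining -= b
        j += 1
    return QuerySchedule(
        initial_fraction=initial_fraction,
        batch_sizes=tuple(batches),
        growth=growth,
    )


def _initial_draw(
    train_indices: Sequence[int],
    labels: dict[int, int],
    fraction: float,
    rng: np.random.Generator,
    stratify: bool,
) -> list[int]:
    n_init = max(2, int(round(fraction * len(train_indices))))
    idx = np.asarray(train_indices)
    if not stratify:
        return sorted(rng.choice(idx, size=n_init, replace=False).tolist())
    pos = idx[[labels[i] == 1 for i in idx]]
    neg = idx[[labels[i] == 0 for i in idx]]
    n_pos = max(1, int(round(n_init * len(pos) / len(idx))))
    n_pos = min(n_pos, len(pos), n_init - 1)
    n_neg = n_init - n_pos
    chosen = np.concatenate(
        [
            rng.choice(pos, size=n_pos, replace=False),
            rng.choice(neg, size=n_neg, replace=False),
        ]
    )
    return sorted(int(i) for i in chosen)


def _run_pool_learning(
    dataset: Sequence[CompoundRecord],
    train_indices: Sequence[int],
    val_indices: Sequence[int],
    config: DMPNNConfig,
    schedule: QuerySchedule,
    seed: int,
    strategy: str,
    stratify_initial: bool = True,
) -> PoolState:
    labels = {i: dataset[i].label for i in train_indices}
    if any(l is None for l in labels.values()):
        raise ValueError("pool learning needs labels for every training index")
    rng = np.random.default_rng(seed)
    init = _initial_draw(train_indices, labels, schedule.initial_fraction, rng, stratify_initial)
    labeled = list(init)
    unlabeled = [i for i in train_indices if i not in set(init)]
    if sum(schedule.batch_sizes) != len(unlabeled):
        raise ValueError(
            f"schedule covers {sum(schedule.batch_sizes)} samples but the "
            f"unlabeled pool holds {len(unlabeled)}"
        )
    val_records = [dataset[i] for i in val_indices]
    y_val = np.asarray([dataset[i].label for i in val_indices])

    state = PoolState(labeled=sorted(labeled), unlabeled=sorted(unlabeled))
    sub_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(schedule.batch_sizes) + 1)

    for it, batch in enumerate(schedule.batch_sizes):
        cfg = DMPNNConfig(**{**config.__dict__, "seed": int(sub_seeds[it])})
        model = train([dataset[i] for i in state.labeled], val_records, cfg)
        val_probs = predict_proba(model, val_records)
        metrics = evaluation.metrics_report(y_val, val_probs)
        state.models.append(model)
        state.history.append(
            {
                "iteration": it,
                "n_labeled": len(state.labeled),
                "val_acc": metrics.acc,
                "val_mcc": metrics.mcc,
                "val_f1": metrics.f1,
            }
        )
        if strategy == "active":
            pool_probs = predict_proba(model, [dataset[i] for i in state.unlabeled])
            picked = select_batch(pool_probs, state.unlabeled, batch)
        else:
            picked = [
                state.unlabeled[j]
                for j in rng.choice(len(state.unlabeled), size=batch, replace=False)
            ]
        picked_set = set(picked)
        state.labeled = sorted(state.labeled + picked)
        state.unlabeled = sorted(i for i in state.unlabeled if i not in picked_set)
        state.iteration = it + 1

    # final model trained on the fully labeled pool
    cfg = DMPNNConfig(**{**config.__dict__, "seed": int(sub_seeds[-1])})
    model = train([dataset[i] for i in state.labeled], val_records, cfg)
    val_probs = predict_proba(model, val_records)
    metrics = evaluation.metrics_report(y_val, val_probs)
    state.models.append(model)
    state.history.append(
        {
            "iteration": state.iteration,
            "n_labeled": len(state.labeled),
            "val_acc": metrics.acc,
            "val_mcc": metrics.mcc,
            "val_f1": metrics.f1,
        }
    )
    state.iteration += 1
    return state


def run_active_learning(
    dataset: Sequence[CompoundRecord],
    train_indices: Sequence[int],
    val_indices: Sequence[int],
    config: DMPNNConfig,
    schedule: QuerySchedule,
    seed: int,
    stratify_initial: bool = True,
) -> PoolState:
    """Uncertainty-sampling active learning over a labeled cache."""
    return _run_pool_learning(
        dataset, train_indices, val_indices, config, schedule, seed, "active", stratify_initial
    )


def run_passive_learning(
    dataset: Sequence[CompoundRecord],
    train_indices: Sequence[int],
    val_indices: Sequence[int],
    config: DMPNNConfig,
    schedule: QuerySchedule,
    seed: int,
    stratify_initial: bool = True,
) -> PoolState:
    """Random-selection baseline with the same batch schedule."""
    return _run_pool_learning(
        dataset, train_indices, val_indices, config, schedule, seed, "passive", stratify_initial
    )


def ensemble_predict(
    ensemble: EnsembleModel, records: Sequence[CompoundRecord]
) -> np.ndarray:
    """Arithmetic mean of member probabilities, per record."""
    if not ensemble.members:
        raise ValueError("empty ensemble")
    preds = np.stack([m.predict_proba(records) for m in ensemble.members])
    # centered mean: exact when all members agree (identity contract), and
    # numerically no worse than the plain mean otherwise
    return preds[0] + (preds - preds[0]).mean(axis=0)


def select_ensemble_size(
    pool_state: PoolState,
    validation_records: Sequence[CompoundRecord],
    max_size: int = 5,
) -> EnsembleModel:
    """Choose N maximizing validation accuracy over last-N-model suffixes.

    Ties go to the smaller N. Candidate ensembles are suffixes of the
    iteration history only: early-iteration models trained on little data
    would dilute the average.
    """
    if not pool_state.models:
        raise ValueError("pool state holds no models")
    y = np.asarray([r.label for r in validation_records], dtype=np.float64)
    if np.any(np.isnan(y)):
        raise ValueError("validation records must be labeled")
    max_size = min(max_size, len(pool_state.models))
    member_preds = np.stack(
        [m.predict_proba(validation_records) for m in pool_state.models[-max_size:]]
    )  # oldest..newest of the suffix
    best_n, best_acc = 1, -1.0
    for n in range(1, max_size + 1):
        avg = member_preds[-n:].mean(axis=0)
        acc = evaluation.acc(evaluation.confusion(y, avg))
        if acc > best_acc + 1e-12:
            best_n, best_acc = n, acc
    return EnsembleModel(members=list(pool_state.models[-best_n:]))
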