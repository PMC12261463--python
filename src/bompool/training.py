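"""Task-level training entry points.

Thin wrappers over the estimators in :mod:`bompool.estimators` that work
from id-keyed label tables and embedding caches (the shapes the CLI and
file formats produce), check that every labeled id has an embedding, and
echo configuration into the run history.

The parameter-fairness harness lives here too: pooling methods are only
comparable when their trainable stages have equal parameter counts, and
:func:`bompool.estimators.assert_parameter_parity` enforces that before
any paired run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np

from .estimators import (
    ContrastiveHomologyEmbedder,
    PooledEmbeddingRegressor,
    TripletSampler,
    assert_parameter_parity,
)
from .providers import TokenEmbeddingMatrix

__all__ = [
    "TrainConfig",
    "TripletSampler",
    "train_regression",
    "train_contrastive",
    "assert_parameter_parity",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by the two task families."""

    task: str = "regression"
    pooling_method: str = "bom"
    window: tuple[int, int] = (5, 5)
    d_pool: int | None = None
    hidden: tuple[int, ...] | None = None
    activation: str = "tanh"
    epochs: int = 200
    learning_rate: float = 0.01
    lr_schedule: str = "constant"
    batch_size: int = 100
    margin: float = 0.6
    patience: int | None = 30
    head_hidden: tuple[int, int] = (256, 64)
    head_dropout: float = 0.3
    head_batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.task not in ("regression", "contrastive"):
            raise ValueError(f"unknown task {self.task!r}")


def _gather(
    labels: Mapping[str, float], embeddings: Mapping[str, TokenEmbeddingMatrix]
):
    ids = sorted(labels)
    missing = [i for i in ids if i not in embeddings]
    if missing:
        raise KeyError(f"no embeddings for ids: {missing}")
    X = [embeddings[i] for i in ids]
    y = np.array([labels[i] for i in ids])
    return ids, X, y


def train_regression(
    labels: Mapping[str, float],
    embeddings: Mapping[str, TokenEmbeddingMatrix],
    cfg: TrainConfig,
    val_labels: Mapping[str, float] | None = None,
) -> PooledEmbeddingRegressor:
    """Jointly optimize pooling transforms and regression head.

    ``labels`` maps sequence ids to real targets; every id must have an
    embedding in ``embeddings``.  Returns the fitted estimator (loss
    history in ``.history_``).
    """
    ids, X, y = _gather(labels, embeddings)
    est = PooledEmbeddingRegressor(
        pooling=cfg.pooling_method,
        k=cfg.window[0],
        s=cfg.window[1],
        d_pool=cfg.d_pool,
        hidden=cfg.hidden,
        activation=cfg.activation,
        head_hidden=cfg.head_hidden,
        head_dropout=cfg.head_dropout,
        head_batch_norm=cfg.head_batch_norm,
        epochs=cfg.epochs,
        lr=cfg.learning_rate,
        lr_schedule=cfg.lr_schedule,
        batch_size=cfg.batch_size,
        patience=cfg.patience,
        random_state=cfg.seed,
    )
    if val_labels is not None:
        _, X_val, y_val = _gather(val_labels, embeddings)
        est.fit(X, y, X_val=X_val, y_val=y_val)
    else:
        est.fit(X, y)
    est.ids_ = ids
    return est


def train_contrastive(
    group_labels: Mapping[str, Hashable],
    embeddings: Mapping[str, TokenEmbeddingMatrix],
    cfg: TrainConfig,
) -> ContrastiveHomologyEmbedder:
    """Contrastive triplet training of pooled representations.

    ``group_labels`` maps sequence ids to relation groups (sequences in
    the same group are positive partners).  Returns the fitted embedder;
    ``.ids_`` records the sequence order used by ``transform``.
    """
    ids, X, y = _gather(group_labels, embeddings)
    est = ContrastiveHomologyEmbedder(
        pooling=cfg.pooling_method,
        k=cfg.window[0],
        s=cfg.window[1],
        d_pool=cfg.d_pool,
        hidden=cfg.hidden,
        activation=cfg.activation,
        margin=cfg.margin,
        epochs=cfg.epochs,
        lr=cfg.learning_rate,
        random_state=cfg.seed,
    )
    est.fit(X, y)
    est.ids_ = ids
    return est
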