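"""Scikit-learn style estimators that jointly optimize pooling and heads.

Three estimators cover the downstream task families:

* :class:`PooledEmbeddingRegressor` — sequence -> real value.  Pools each
  per-residue embedding matrix with the chosen operator (trainable Cls /
  Eos / Avg, full attention, or BoM) and feeds a 3-layer head; pooling
  transforms and head are optimized together against mean-squared error.
* :class:`ContrastiveHomologyEmbedder` — fit on sequences with group
  labels (e.g. superfamily); learns pooled representations via triplet
  loss so related sequences land close in cosine distance.  ``transform``
  returns the learned representations.
* :class:`CrossAttentionInteractionModel` — domain-peptide interaction
  via cross-attention BoM pooling with pair-dependent representations and
  triplet loss (domain anchor, positive/negative peptides).

All estimators follow sklearn conventions: constructor arguments stored
verbatim, fitted state in trailing-underscore attributes, ``get_params`` /
``set_params`` inherited from ``BaseEstimator``, full determinism from
``random_state``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .autodiff import Adam, Tensor, concat
from .heads import RegressionHead, RegressionHeadConfig, Triplet, cosine_distance
from .pooling import (
    PoolingParams,
    WindowConfig,
    attention_pool_core,
    bag_matrix,
    pool_avg,
    pool_cls,
    pool_eos,
    trainable_global_core,
)
from .providers import TokenEmbeddingMatrix

__all__ = [
    "TripletSampler",
    "PooledEmbeddingRegressor",
    "ContrastiveHomologyEmbedder",
    "CrossAttentionInteractionModel",
    "pooling_parameter_count",
    "assert_parameter_parity",
]

logger = logging.getLogger(__name__)

_GLOBAL_METHODS = ("cls", "eos", "avg")
_BAG_METHODS = ("attention", "bom")


# ---------------------------------------------------------------------------
# shared helpers


def _residue_rows(x) -> np.ndarray:
    if isinstance(x, TokenEmbeddingMatrix):
        return x.residue_values()
    return np.asarray(x, dtype=np.float64)


def _vanilla_pooled(x, method: str) -> np.ndarray:
    if method == "avg":
        return pool_avg(x).values
    if method == "cls":
        return pool_cls(x).values
    return pool_eos(x).values


def _row_cosine_distance(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    """Cosine distance per row of two (B, d) tensors."""
    dot = (a * b).sum(axis=1)
    na = ((a * a).sum(axis=1) + eps).sqrt()
    nb = ((b * b).sum(axis=1) + eps).sqrt()
    return 1.0 - dot / (na * nb)


class _PoolingStack:
    """Precomputed pooling inputs plus batched differentiable forward."""

    def __init__(self, X, method: str, window: WindowConfig):
        self.method = method
        if method in _GLOBAL_METHODS:
            self.base = np.vstack([_vanilla_pooled(x, method) for x in X])
            self.d = self.base.shape[1]
        elif method in _BAG_METHODS:
            w = window if method == "bom" else WindowConfig(1, 1)
            self.bags = [bag_matrix(x, w) for x in X]
            self.d = self.bags[0].shape[1]
        else:
            raise ValueError(f"unknown pooling method {method!r}")

    def __len__(self) -> int:
        return self.base.shape[0] if self.method in _GLOBAL_METHODS else len(self.bags)

    def forward(self, idx: np.ndarray, params: PoolingParams):
        """Pooled tensors for ``idx``; returns (pooled, order) where
        ``order`` lists the original indices row-for-row (bag batching
        groups sequences by window count)."""
        idx = np.asarray(idx)
        if self.method in _GLOBAL_METHODS:
            return trainable_global_core(self.base[idx], params), idx
        groups: dict[int, list[int]] = {}
        for j in idx:
            groups.setdefault(self.bags[j].shape[0], []).append(int(j))
        parts, order = [], []
        for n in sorted(groups):
            js = groups[n]
            stack = np.stack([self.bags[j] for j in js])
            parts.append(attention_pool_core(stack, stack, params))
            order.extend(js)
        pooled = parts[0] if len(parts) == 1 else concat(parts, axis=0)
        return pooled, np.asarray(order)


def pooling_parameter_count(
    method: str,
    d: int,
    d_pool: int | None = None,
    hidden: tuple[int, ...] | None = None,
    activation: str = "tanh",
) -> int:
    """Trainable-parameter count of a pooling operator's Q/K/V triple."""
    if method not in _GLOBAL_METHODS + _BAG_METHODS:
        raise ValueError(f"unknown pooling method {method!r}")
    return PoolingParams.init(d, d_pool, hidden, activation, seed=0).n_params


def assert_parameter_parity(methods, d, d_pool=None, hidden=None, activation="tanh"):
    """Fail unless every method's pooling stage has the same trainable
    parameter count (the fairness precondition for comparing them)."""
    counts = {
        m: pooling_parameter_count(m, d, d_pool, hidden, activation) for m in methods
    }
    if len(set(counts.values())) != 1:
        raise AssertionError(f"unequal trainable parameter counts: {counts}")
    return counts


# ---------------------------------------------------------------------------
# regression


class PooledEmbeddingRegressor(BaseEstimator, RegressorMixin):
    """Regression on pooled per-residue embeddings.

    Parameters
    ----------
    pooling : {"bom", "attention", "avg", "cls", "eos"}
        Pooling operator.  "attention" is full attention pooling (BoM with
        k=1, s=1); "avg"/"cls"/"eos" are the trainable-augmented global
        operators ``Q(v)+K(v)+V(v)``, which carry the same number of
        trainable parameters as the attention variants.
    k, s, tail
        Window settings for BoM pooling.
    d_pool, hidden, activation
        Q/K/V transform architecture (default: one hidden tanh layer,
        ``d -> d_pool -> d_pool``).
    head_hidden, head_dropout, head_batch_norm
        Regression head architecture (default 256/64, dropout 0.3).
    epochs, lr, lr_schedule, batch_size, patience
        Adam optimization budget; ``lr_schedule`` is ``"constant"`` or
        ``"cosine"`` (decay to lr/20 over the epoch budget).  Early
        stopping on validation loss when a validation set is passed to
        :meth:`fit` (``patience=None`` disables it).
    random_state
        Seeds parameter initialization, batching and dropout; fitting is a
        pure function of (data, parameters, random_state).
    """

    def __init__(
        self,
        pooling: str = "bom",
        k: int = 5,
        s: int = 5,
        tail: bool = True,
        d_pool: int | None = None,
        hidden: tuple[int, ...] | None = None,
        activation: str = "tanh",
        head_hidden: tuple[int, int] = (256, 64),
        head_dropout: float = 0.3,
        head_batch_norm: bool = True,
        epochs: int = 200,
        lr: float = 0.01,
        lr_schedule: str = "constant",
        weight_decay: float = 0.0,
        batch_size: int = 100,
        patience: int | None = 30,
        random_state: int = 0,
    ):
        self.pooling = pooling
        self.k = k
        self.s = s
        self.tail = tail
        self.d_pool = d_pool
        self.hidden = hidden
        self.activation = activation
        self.head_hidden = head_hidden
        self.head_dropout = head_dropout
        self.head_batch_norm = head_batch_norm
        self.epochs = epochs
        self.lr = lr
        self.lr_schedule = lr_schedule
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.patience = patience
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _window(self) -> WindowConfig:
        return WindowConfig(self.k, self.s, self.tail)

    def _snapshot(self):
        return (
            [p.value.copy() for p in self.pooling_params_.parameters()],
            self.head_.state_dict(),
        )

    def _restore(self, snap):
        for p, v in zip(self.pooling_params_.parameters(), snap[0]):
            p.value = v.copy()
        self.head_.load_state_dict(snap[1])

    def _predict_stack(self, stack: _PoolingStack) -> np.ndarray:
        idx = np.arange(len(stack))
        pooled, order = stack.forward(idx, self.pooling_params_)
        preds = self.head_.forward(pooled.value, training=False).value
        out = np.empty(len(stack))
        out[order] = preds
        return out

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on a list of embedding matrices and real-valued labels.

        ``X_val``/``y_val`` enable per-epoch validation tracking and early
        stopping; without them the full budget of epochs is used.
        """
        y = np.asarray(y, dtype=float)
        if len(X) != y.size or y.size == 0:
            raise ValueError("X and y must be equally long and non-empty")
        stack = _PoolingStack(X, self.pooling, self._window())
        ss = np.random.SeedSequence(self.random_state)
        s_init, s_head, s_batch, s_drop = ss.spawn(4)
        d_pool = self.d_pool or stack.d
        self.pooling_params_ = PoolingParams.init(
            stack.d,
            d_pool,
            self.hidden,
            self.activation,
            seed=np.random.default_rng(s_init),
        )
        self.head_ = RegressionHead(
            RegressionHeadConfig(
                d_pool, tuple(self.head_hidden), self.head_dropout, self.head_batch_norm
            ),
            seed=int(s_head.generate_state(1)[0] % 2**31),
        )
        opt = Adam(
            [*self.pooling_params_.parameters(), *self.head_.parameters()],
            lr=self.lr,
            weight_decay=self.weight_decay,
        )
        rng_batch = np.random.default_rng(s_batch)
        rng_drop = np.random.default_rng(s_drop)
        val_stack = (
            _PoolingStack(X_val, self.pooling, self._window())
            if X_val is not None
            else None
        )
        n = y.size
        history = []
        best = (np.inf, 0, None)
        for epoch in range(self.epochs):
            if self.lr_schedule == "cosine":
                lo_lr = self.lr / 20.0
                epoch_lr = lo_lr + 0.5 * (self.lr - lo_lr) * (
                    1.0 + np.cos(np.pi * epoch / max(self.epochs - 1, 1))
                )
            elif self.lr_schedule == "constant":
                epoch_lr = self.lr
            else:
                raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
            perm = rng_batch.permutation(n)
            train_loss = 0.0
            for lo in range(0, n, self.batch_size):
                idx = perm[lo : lo + self.batch_size]
                if idx.size < 2 and self.head_batch_norm:
                    continue  # leftover singleton cannot feed train-mode BN
                pooled, order = stack.forward(idx, self.pooling_params_)
                preds = self.head_.forward(pooled, training=True, rng=rng_drop)
                loss = ((preds - y[order]) ** 2).mean()
                opt.zero_grad()
                loss.backward()
                opt.step(lr=epoch_lr)
                train_loss += float(loss.value) * idx.size
            row = {"epoch": epoch, "train_mse": train_loss / n}
            if val_stack is not None:
                val_preds = self._predict_stack(val_stack)
                row["val_mse"] = float(np.mean((val_preds - np.asarray(y_val)) ** 2))
                if row["val_mse"] < best[0] - 1e-12:
                    best = (row["val_mse"], epoch, self._snapshot())
            history.append(row)
            if (
                val_stack is not None
                and self.patience is not None
                and epoch - best[1] >= self.patience
            ):
                break
        if best[2] is not None:
            self._restore(best[2])
            self.best_epoch_ = best[1]
        self.history_ = pd.DataFrame(history)
        self.n_pooling_params_ = self.pooling_params_.n_params
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "head_"):
            raise RuntimeError("estimator is not fitted")
        return self._predict_stack(_PoolingStack(X, self.pooling, self._window()))


# ---------------------------------------------------------------------------
# contrastive homology embedding


class TripletSampler:
    """Seeded per-epoch triplet sampling over anchors.

    Each epoch cycles through every anchor once and draws one positive and
    one negative partner uniformly from the anchor's relation lists.
    Anchors lacking either are skipped (counted in ``n_skipped``).
    """

    def __init__(
        self,
        positives: dict[str, list[str]],
        negatives: dict[str, list[str]],
        seed: int = 0,
    ):
        self.positives = positives
        self.negatives = negatives
        self.anchors = sorted(positives.keys() | negatives.keys())
        self._rng = np.random.default_rng(seed)
        self.n_skipped = 0
        usable = [a for a in self.anchors if positives.get(a) and negatives.get(a)]
        if not usable:
            raise ValueError("no anchor has both a positive and a negative partner")

    def sample_epoch(self) -> list[Triplet]:
        triplets = []
        for a in self.anchors:
            pos = self.positives.get(a) or []
            neg = self.negatives.get(a) or []
            if not pos or not neg:
                self.n_skipped += 1
                logger.info("anchor %s lacks a positive or negative partner", a)
                continue
            p = pos[self._rng.integers(len(pos))]
            n = neg[self._rng.integers(len(neg))]
            triplets.append(Triplet(a, p, n))
        return triplets


class ContrastiveHomologyEmbedder(BaseEstimator, TransformerMixin):
    """Learn pooled sequence representations with contrastive triplets.

    ``fit(X, y)`` takes embedding matrices and group labels ``y`` (e.g.
    superfamily identifiers): sequences sharing a label are positive
    partners, all others negative.  Training minimizes the cosine triplet
    loss ``max(0, Δ(a,p) - Δ(a,n) + margin)`` over the pooled vectors,
    one sampled triplet per anchor per epoch.
    """

    def __init__(
        self,
        pooling: str = "bom",
        k: int = 5,
        s: int = 5,
        tail: bool = True,
        d_pool: int | None = None,
        hidden: tuple[int, ...] | None = None,
        activation: str = "tanh",
        margin: float = 0.6,
        epochs: int = 200,
        lr: float = 0.01,
        random_state: int = 0,
    ):
        self.pooling = pooling
        self.k = k
        self.s = s
        self.tail = tail
        self.d_pool = d_pool
        self.hidden = hidden
        self.activation = activation
        self.margin = margin
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    def _window(self) -> WindowConfig:
        return WindowConfig(self.k, self.s, self.tail)

    def fit(self, X, y):
        y = np.asarray(y)
        if len(X) != y.size:
            raise ValueError("X and y must be equally long")
        stack = _PoolingStack(X, self.pooling, self._window())
        ss = np.random.SeedSequence(self.random_state)
        s_init, s_sample = ss.spawn(2)
        d_pool = self.d_pool or stack.d
        self.pooling_params_ = PoolingParams.init(
            stack.d,
            d_pool,
            self.hidden,
            self.activation,
            seed=np.random.default_rng(s_init),
        )
        names = [str(i) for i in range(y.size)]
        positives = {
            names[i]: [names[j] for j in range(y.size) if j != i and y[j] == y[i]]
            for i in range(y.size)
        }
        negatives = {
            names[i]: [names[j] for j in range(y.size) if y[j] != y[i]]
            for i in range(y.size)
        }
        sampler = TripletSampler(
            positives, negatives, seed=int(s_sample.generate_state(1)[0] % 2**31)
        )
        opt = Adam(self.pooling_params_.parameters(), lr=self.lr)
        all_idx = np.arange(y.size)
        history = []
        for epoch in range(self.epochs):
            triplets = sampler.sample_epoch()
            pooled, order = stack.forward(all_idx, self.pooling_params_)
            pos_in_order = np.empty(y.size, dtype=int)
            pos_in_order[order] = np.arange(y.size)
            a_idx = pos_in_order[[int(t.anchor_id) for t in triplets]]
            p_idx = pos_in_order[[int(t.positive_id) for t in triplets]]
            n_idx = pos_in_order[[int(t.negative_id) for t in triplets]]
            d_pos = _row_cosine_distance(pooled[a_idx], pooled[p_idx])
            d_neg = _row_cosine_distance(pooled[a_idx], pooled[n_idx])
            loss = (d_pos - d_neg + self.margin).relu().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append({"epoch": epoch, "triplet_loss": float(loss.value)})
        self.history_ = pd.DataFrame(history)
        self.n_pooling_params_ = self.pooling_params_.n_params
        self.sampler_ = sampler
        return self

    def transform(self, X) -> np.ndarray:
        """Pooled representation of each sequence under the trained params."""
        if not hasattr(self, "pooling_params_"):
            raise RuntimeError("estimator is not fitted")
        stack = _PoolingStack(X, self.pooling, self._window())
        pooled, order = stack.forward(np.arange(len(stack)), self.pooling_params_)
        out = np.empty_like(pooled.value)
        out[order] = pooled.value
        return out


# ---------------------------------------------------------------------------
# cross-attention interaction model


class CrossAttentionInteractionModel(BaseEstimator):
    """Domain-peptide interaction detection with cross-attention BoM.

    Representations are pair-dependent: a pair (domain D, peptide P) is
    scored by ``-Δ(P_CBoM(D|P), P_CBoM(P|D))``.  Peptides shorter than the
    window ``k`` contribute a single whole-sequence window.  Training uses
    triplets (domain anchor, interacting peptide, non-interacting peptide)
    and cycles through all domains each epoch.
    """

    def __init__(
        self,
        k: int = 30,
        s: int = 10,
        tail: bool = True,
        d_pool: int | None = None,
        hidden: tuple[int, ...] | None = None,
        activation: str = "tanh",
        margin: float = 0.6,
        epochs: int = 150,
        lr: float = 0.01,
        random_state: int = 0,
    ):
        self.k = k
        self.s = s
        self.tail = tail
        self.d_pool = d_pool
        self.hidden = hidden
        self.activation = activation
        self.margin = margin
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    def _window(self) -> WindowConfig:
        return WindowConfig(self.k, self.s, self.tail)

    def _pair_distance(self, bag_a: np.ndarray, bag_b: np.ndarray):
        ra = attention_pool_core(bag_a, bag_b, self.pooling_params_)
        rb = attention_pool_core(bag_b, bag_a, self.pooling_params_)
        return cosine_distance(ra, rb)

    def fit(self, domains: dict, peptides: dict, interactions: pd.DataFrame):
        """Fit from id -> embedding-matrix mappings and an interaction table
        with columns domain_id, peptide_id, interacting."""
        w = self._window()
        self.domain_bags_ = {i: bag_matrix(m, w) for i, m in domains.items()}
        self.peptide_bags_ = {i: bag_matrix(m, w) for i, m in peptides.items()}
        d = next(iter(self.domain_bags_.values())).shape[1]
        ss = np.random.SeedSequence(self.random_state)
        s_init, s_sample = ss.spawn(2)
        self.pooling_params_ = PoolingParams.init(
            d,
            self.d_pool or d,
            self.hidden,
            self.activation,
            seed=np.random.default_rng(s_init),
        )
        positives = {
            did: sub[sub["interacting"]]["peptide_id"].tolist()
            for did, sub in interactions.groupby("domain_id")
        }
        negatives = {
            did: sub[~sub["interacting"]]["peptide_id"].tolist()
            for did, sub in interactions.groupby("domain_id")
        }
        sampler = TripletSampler(
            positives, negatives, seed=int(s_sample.generate_state(1)[0] % 2**31)
        )
        opt = Adam(self.pooling_params_.parameters(), lr=self.lr)
        history = []
        for epoch in range(self.epochs):
            triplets = sampler.sample_epoch()
            loss = None
            for t in triplets:
                ba = self.domain_bags_[t.anchor_id]
                d_pos = self._pair_distance(ba, self.peptide_bags_[t.positive_id])
                d_neg = self._pair_distance(ba, self.peptide_bags_[t.negative_id])
                term = (d_pos - d_neg + self.margin).relu()
                loss = term if loss is None else loss + term
            loss = loss / len(triplets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append({"epoch": epoch, "triplet_loss": float(loss.value)})
        self.history_ = pd.DataFrame(history)
        self.sampler_ = sampler
        return self

    def likelihood(self, domain_id: str, peptide_id: str) -> float:
        """Interaction likelihood: minus the pair-dependent cosine distance."""
        if not hasattr(self, "pooling_params_"):
            raise RuntimeError("estimator is not fitted")
        return float(
            -self._pair_distance(
                self.domain_bags_[domain_id], self.peptide_bags_[peptide_id]
            ).value
        )

    def score_pairs(self, interactions: pd.DataFrame) -> pd.DataFrame:
        """Attach a ``likelihood`` column to a domain/peptide pair table."""
        out = interactions.copy()
        out["likelihood"] = [
            self.likelihood(d, p)
            for d, p in zip(out["domain_id"], out["peptide_id"])
        ]
        return out
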