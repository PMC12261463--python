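"""Downstream prediction heads and training objectives.

Two task families sit on top of a pooled representation:

* real-valued sequence property prediction — a 3-layer feed-forward head
  ``d_pool -> 256 -> 64 -> 1`` with batch normalization and dropout 0.3
  between layers, trained with mean-squared error;
* pairwise tasks (homology, interaction) — contrastive triplet learning
  with cosine distance ``Δ(u, v) = 1 - u·v / (‖u‖‖v‖)`` and margin ``m``
  (default 0.6): ``max(0, Δ(a, p) - Δ(a, n) + m)``.

For cross-attention BoM pooling the triplet distances are pair-dependent:
``Δ(P_CBoM(Ha|Hp), P_CBoM(Hp|Ha))`` replaces ``Δ(P(Ha), P(Hp))``, so the
anchor is re-pooled against each partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor
from .pooling import PoolingParams, WindowConfig, attention_pool_core, bag_matrix

__all__ = [
    "RegressionHeadConfig",
    "RegressionHead",
    "ContrastiveConfig",
    "Triplet",
    "mse_loss",
    "cosine_distance",
    "triplet_loss",
    "cross_bom_triplet_loss",
]

_ZERO_NORM_TOL = 1e-9


@dataclass(frozen=True)
class RegressionHeadConfig:
    """Architecture of the regression head (three affine layers)."""

    d_pool: int
    hidden_dims: tuple[int, int] = (256, 64)
    dropout: float = 0.3
    batch_norm: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.d_pool < 1 or any(h < 1 for h in self.hidden_dims):
            raise ValueError("all layer dimensions must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class ContrastiveConfig:
    """Triplet-loss settings: margin ``m`` and cosine-distance epsilon."""

    margin: float = 0.6
    eps: float = 1e-12

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass(frozen=True)
class Triplet:
    """Anchor/positive/negative sequence references for contrastive training."""

    anchor_id: str
    positive_id: str
    negative_id: str

    def __post_init__(self):
        if len({self.anchor_id, self.positive_id, self.negative_id}) != 3:
            raise ValueError("triplet references must be three distinct ids")


class RegressionHead:
    """3-layer feed-forward regression head.

    Layer pattern per hidden block: affine, batch normalization (per-batch
    statistics in train mode, running averages in eval mode), activation,
    dropout.  Train mode with batch normalization needs a batch of at
    least 2.
    """

    def __init__(self, cfg: RegressionHeadConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        dims = [cfg.d_pool, *cfg.hidden_dims, 1]
        self.weights: list[Parameter] = []
        self.biases: list[Parameter] = []
        for a, b in zip(dims[:-1], dims[1:]):
            self.weights.append(Parameter(rng.normal(0, 1 / np.sqrt(a), size=(a, b))))
            self.biases.append(Parameter(np.zeros(b)))
        self.gammas: list[Parameter] = []
        self.betas: list[Parameter] = []
        self._run_mean: list[np.ndarray] = []
        self._run_var: list[np.ndarray] = []
        if cfg.batch_norm:
            for h in cfg.hidden_dims:
                self.gammas.append(Parameter(np.ones(h)))
                self.betas.append(Parameter(np.zeros(h)))
                self._run_mean.append(np.zeros(h))
                self._run_var.append(np.ones(h))
        self._bn_momentum = 0.1
        self._bn_eps = 1e-5

    def parameters(self) -> list[Parameter]:
        return [*self.weights, *self.biases, *self.gammas, *self.betas]

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        """Predict one scalar per input row; returns a ``(B,)`` tensor.

        ``training=True`` uses per-batch normalization statistics and
        applies dropout with the supplied ``rng`` (seeded determinism).
        """
        t = as_tensor(x)
        single = t.ndim == 1
        if single:
            t = t.reshape(1, -1)
        if t.shape[-1] != self.cfg.d_pool:
            raise ValueError(f"head expects {self.cfg.d_pool}-vectors, got {t.shape}")
        if training and self.cfg.batch_norm and t.shape[0] < 2:
            raise ValueError("train mode with batch normalization needs batch size >= 2")
        if training and self.cfg.dropout > 0 and rng is None:
            rng = np.random.default_rng(0)
        n_hidden = len(self.cfg.hidden_dims)
        for i in range(n_hidden):
            t = t @ self.weights[i] + self.biases[i]
            if self.cfg.batch_norm:
                if training:
                    mu = t.mean(axis=0)
                    var = ((t - mu) ** 2).mean(axis=0)
                    m = self._bn_momentum
                    self._run_mean[i] = (1 - m) * self._run_mean[i] + m * mu.value
                    self._run_var[i] = (1 - m) * self._run_var[i] + m * var.value
                    t = (t - mu) / ((var + self._bn_eps) ** 0.5)
                else:
                    t = (t - self._run_mean[i]) / np.sqrt(self._run_var[i] + self._bn_eps)
                t = t * self.gammas[i] + self.betas[i]
            t = t.relu() if self.cfg.activation == "relu" else t.tanh()
            if training and self.cfg.dropout > 0:
                keep = rng.random(t.shape) >= self.cfg.dropout
                t = t * (keep / (1.0 - self.cfg.dropout))
        t = t @ self.weights[-1] + self.biases[-1]
        t = t.reshape(-1)
        return t[0] if single else t

    __call__ = forward

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            state[f"W{i}"] = w.value.copy()
            state[f"b{i}"] = b.value.copy()
        for i in range(len(self.gammas)):
            state[f"gamma{i}"] = self.gammas[i].value.copy()
            state[f"beta{i}"] = self.betas[i].value.copy()
            state[f"run_mean{i}"] = self._run_mean[i].copy()
            state[f"run_var{i}"] = self._run_var[i].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i in range(len(self.weights)):
            self.weights[i].value = np.asarray(state[f"W{i}"], dtype=np.float64)
            self.biases[i].value = np.asarray(state[f"b{i}"], dtype=np.float64)
        for i in range(len(self.gammas)):
            self.gammas[i].value = np.asarray(state[f"gamma{i}"], dtype=np.float64)
            self.betas[i].value = np.asarray(state[f"beta{i}"], dtype=np.float64)
            self._run_mean[i] = np.asarray(state[f"run_mean{i}"], dtype=np.float64)
            self._run_var[i] = np.asarray(state[f"run_var{i}"], dtype=np.float64)


# ---------------------------------------------------------------------------
# losses


def _vec(x):
    """Coerce loss inputs (PooledVector / ndarray / Tensor) to a tensor."""
    if hasattr(x, "values") and not isinstance(x, Tensor):
        x = x.values
    return as_tensor(x)


def mse_loss(pred, target):
    """Mean of squared residuals over paired prediction/target vectors."""
    p = _vec(pred).reshape(-1)
    t = _vec(target).reshape(-1)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.value.size == 0:
        raise ValueError("mse_loss needs at least one pair")
    return ((p - t) ** 2).mean()


def cosine_distance(u, v, eps: float = 1e-12):
    """Cosine distance ``1 - u·v / (‖u‖ ‖v‖)`` in [0, 2].

    Rejects (near-)zero-norm inputs outright; ``eps`` additionally guards
    the norms inside the differentiable expression.
    """
    ut, vt = _vec(u), _vec(v)
    for name, t in (("first", ut), ("second", vt)):
        if np.linalg.norm(t.value) < _ZERO_NORM_TOL:
            raise ValueError(
                f"cosine distance undefined: {name} vector has norm below "
                f"the {_ZERO_NORM_TOL:g} tolerance"
            )
    dot = (ut * vt).sum()
    nu = ((ut * ut).sum() + eps).sqrt()
    nv = ((vt * vt).sum() + eps).sqrt()
    return 1.0 - dot / (nu * nv)


def triplet_loss(pa, pp, pn, cfg: ContrastiveConfig = ContrastiveConfig()):
    """Contrastive triplet loss ``max(0, Δ(a,p) - Δ(a,n) + m)``."""
    d_pos = cosine_distance(pa, pp, cfg.eps)
    d_neg = cosine_distance(pa, pn, cfg.eps)
    return (d_pos - d_neg + cfg.margin).relu()


def cross_bom_triplet_loss(
    Ha,
    Hp,
    Hn,
    cfg_w: WindowConfig,
    params: PoolingParams,
    cfg_c: ContrastiveConfig = ContrastiveConfig(),
):
    """Triplet loss with pair-dependent cross-attention BoM representations.

    Both arguments of each distance are re-pooled against the partner:
    ``max(0, Δ(P_CBoM(Ha|Hp), P_CBoM(Hp|Ha))
            - Δ(P_CBoM(Ha|Hn), P_CBoM(Hn|Ha)) + m)``.
    """
    ba = bag_matrix(Ha, cfg_w)
    bp = bag_matrix(Hp, cfg_w)
    bn = bag_matrix(Hn, cfg_w)
    d_pos = cosine_distance(
        attention_pool_core(ba, bp, params),
        attention_pool_core(bp, ba, params),
        cfg_c.eps,
    )
    d_neg = cosine_distance(
        attention_pool_core(ba, bn, params),
        attention_pool_core(bn, ba, params),
        cfg_c.eps,
    )
    return (d_pos - d_neg + cfg_c.margin).relu()
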