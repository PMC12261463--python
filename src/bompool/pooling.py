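"""Pooling operators for per-residue embedding matrices.

Global pooling (Cls / Eos / Avg), their trainable augmentations, learnable
self- and cross-attention pooling, windowed local average pooling, and the
hierarchical bag-of-mer (BoM) pooling that composes the last two:

* ``P_CLS(H) = h_1``, ``P_EoS(H) = h_l``, ``P_Avg(H) = mean_i h_i``
* self-attention pooling: the uniform row-average of
  ``softmax(Q(H) K(H)^T / sqrt(d_pool)) V(H)``
* cross-attention pooling: same with queries from one sequence and
  keys/values from the other (asymmetric in its two arguments)
* local average pooling: sliding k-mer windows with stride s, each reduced
  to its arithmetic mean (a :class:`KmerBag`)
* BoM pooling: attention pooling applied to the k-mer bag instead of the
  raw tokens, cutting the attention matrix from l^2 to n(l,s,k)^2 entries.
  With k=1, s=1 the bag is the token matrix itself, so BoM pooling is
  exactly full attention pooling.

Window dialect: the bag holds all complete windows (start positions
``s(i-1)+1``, 1-based) plus, by default, one shorter tail window covering
any residues left after the last complete window; sequences shorter than k
contribute a single whole-sequence window.  ``count_windows`` reports the
number of windows actually emitted.

The Q/K/V maps are small trainable MLPs (:class:`MLPTransform`); when any
of them carries gradients the operators return autodiff tensors internally,
so pooling parameters can be optimized jointly with a downstream head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor, softmax
from .providers import TokenEmbeddingMatrix

__all__ = [
    "WindowConfig",
    "KmerBag",
    "MLPTransform",
    "PoolingParams",
    "PooledVector",
    "pool_cls",
    "pool_eos",
    "pool_avg",
    "trainable_global_pool",
    "trainable_global_core",
    "attention_weights",
    "self_attention_pool",
    "cross_attention_pool",
    "count_windows",
    "count_windows_printed_formula",
    "local_avg_pool",
    "bom_self_pool",
    "bom_cross_pool",
    "attention_pool_core",
    "bag_matrix",
]


# ---------------------------------------------------------------------------
# configuration / containers


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window settings: window length ``k``, stride ``s``.

    ``tail`` appends one shorter window over residues the complete windows
    leave uncovered, so every token belongs to at least one window.
    """

    k: int
    s: int
    tail: bool = True

    def __post_init__(self):
        if self.k < 1 or self.s < 1:
            raise ValueError("window length k and stride s must be >= 1")


@dataclass
class KmerBag:
    """Stack of windowed local averages with 1-based window coordinates."""

    omegas: np.ndarray  # (n, d) window means
    starts: np.ndarray  # (n,) 1-based inclusive start positions
    lengths: np.ndarray  # (n,) tokens covered by each window
    k: int
    s: int

    @property
    def n(self) -> int:
        return self.omegas.shape[0]

    @property
    def ends(self) -> np.ndarray:
        """1-based inclusive end positions."""
        return self.starts + self.lengths - 1


@dataclass
class PooledVector:
    """A fixed-size sequence representation and the operator that made it."""

    values: np.ndarray
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"pooled vector from {self.method!r} has non-finite entries")


# ---------------------------------------------------------------------------
# learnable transforms


class MLPTransform:
    """A small feed-forward map ``R^d_in -> R^d_out``.

    Default architecture is one hidden tanh layer; ``hidden=()`` gives a
    plain affine map.  Works on numpy arrays or autodiff tensors alike and
    broadcasts over leading batch axes.
    """

    def __init__(self, weights, biases, activation: str = "tanh"):
        if activation not in ("tanh", "relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.weights = [p if isinstance(p, Parameter) else Parameter(p) for p in weights]
        self.biases = [p if isinstance(p, Parameter) else Parameter(p) for p in biases]
        self.activation = activation

    @classmethod
    def init(
        cls,
        d_in: int,
        d_out: int,
        hidden: tuple[int, ...] = None,
        activation: str = "tanh",
        rng: np.random.Generator | None = None,
    ) -> "MLPTransform":
        if hidden is None:
            hidden = (d_out,)
        rng = rng or np.random.default_rng()
        dims = [d_in, *hidden, d_out]
        weights, biases = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            weights.append(rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b)))
            biases.append(np.zeros(b))
        return cls(weights, biases, activation)

    @classmethod
    def zeros(cls, d_in: int, d_out: int) -> "MLPTransform":
        """Affine map with all-zero weights and biases (annihilates input)."""
        return cls([np.zeros((d_in, d_out))], [np.zeros(d_out)], "linear")

    @classmethod
    def identity(cls, d: int) -> "MLPTransform":
        """The identity map on R^d (affine, unit weight, zero bias)."""
        return cls([np.eye(d)], [np.zeros(d)], "linear")

    @classmethod
    def constant(cls, d_in: int, value: np.ndarray) -> "MLPTransform":
        """Map sending every input to the fixed vector ``value``."""
        value = np.atleast_1d(np.asarray(value, dtype=np.float64))
        return cls([np.zeros((d_in, value.size))], [value], "linear")

    @property
    def d_in(self) -> int:
        return self.weights[0].value.shape[0]

    @property
    def d_out(self) -> int:
        return self.weights[-1].value.shape[1]

    def parameters(self) -> list[Parameter]:
        return [*self.weights, *self.biases]

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def __call__(self, x):
        t = as_tensor(x)
        if t.shape[-1] != self.d_in:
            raise ValueError(f"transform expects {self.d_in}-vectors, got {t.shape}")
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            t = t @ w + b
            if i < n_layers - 1:
                if self.activation == "tanh":
                    t = t.tanh()
                elif self.activation == "relu":
                    t = t.relu()
        return t


@dataclass
class PoolingParams:
    """The learnable Q/K/V transformation triple for attention pooling.

    Three unshared maps ``R^d -> R^d_pool``; ``scale`` is the softmax
    denominator (default ``sqrt(d_pool)``, the dimension of the query/key
    product space).
    """

    Q: MLPTransform
    K: MLPTransform
    V: MLPTransform
    scale: float | None = None

    def __post_init__(self):
        dims = {t.d_in for t in (self.Q, self.K, self.V)}
        outs = {t.d_out for t in (self.Q, self.K, self.V)}
        if len(dims) != 1 or len(outs) != 1:
            raise ValueError("Q, K, V must share input and output dimensions")

    @classmethod
    def init(
        cls,
        d: int,
        d_pool: int | None = None,
        hidden: tuple[int, ...] | None = None,
        activation: str = "tanh",
        seed: int | np.random.Generator = 0,
        scale: float | None = None,
        qk_init_scale: float = 0.0,
    ) -> "PoolingParams":
        """Seeded random initialization of the Q/K/V triple.

        The output layer of Q is scaled by ``qk_init_scale`` (default 0):
        attention starts exactly uniform, so optimization first shapes the
        value pathway (a set-average of window features) and sharpens
        attention only as the loss demands it.  Q's gradient is nonzero
        from the first step (it flows through K's features), so the
        attention pathway remains fully trainable; zeroing K as well would
        stall both.
        """
        d_pool = d_pool or d
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        make = lambda: MLPTransform.init(d, d_pool, hidden, activation, rng)
        Q, K, V = make(), make(), make()
        Q.weights[-1].value *= qk_init_scale
        return cls(Q, K, V, scale)

    @property
    def d(self) -> int:
        return self.Q.d_in

    @property
    def d_pool(self) -> int:
        return self.Q.d_out

    @property
    def softmax_scale(self) -> float:
        return self.scale if self.scale is not None else float(np.sqrt(self.d_pool))

    def parameters(self) -> list[Parameter]:
        return [*self.Q.parameters(), *self.K.parameters(), *self.V.parameters()]

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))


# ---------------------------------------------------------------------------
# helpers


def _rows(H, include_special: bool = False) -> np.ndarray:
    """Token rows of ``H`` as an array, masking special rows by default."""
    if isinstance(H, TokenEmbeddingMatrix):
        rows = H.values if include_special else H.residue_values()
    else:
        rows = np.asarray(H, dtype=np.float64)
    if rows.ndim != 2:
        raise ValueError("expected an l x d matrix of token embeddings")
    if rows.shape[0] == 0:
        raise ValueError("no token rows left after special-token masking")
    return rows


def _value(x) -> np.ndarray:
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# global pooling


def pool_cls(H: TokenEmbeddingMatrix) -> PooledVector:
    """The embedding of the leading classification token."""
    if not getattr(H, "has_cls", False):
        raise ValueError("Cls-Pooling requires a matrix with a [Cls] row")
    return PooledVector(H.values[0].copy(), "cls")


def pool_eos(H: TokenEmbeddingMatrix) -> PooledVector:
    """The embedding of the trailing end-of-sequence token."""
    if not getattr(H, "has_eos", False):
        raise ValueError("Eos-Pooling requires a matrix with an [EoS] row")
    return PooledVector(H.values[-1].copy(), "eos")


def pool_avg(H, include_special: bool = False) -> PooledVector:
    """Arithmetic mean of the token rows (special rows masked by default)."""
    rows = _rows(H, include_special)
    return PooledVector(rows.mean(axis=0), "avg")


_GLOBAL_BASES = {"cls": pool_cls, "eos": pool_eos, "avg": pool_avg}


def trainable_global_pool(
    H, base: str, params: PoolingParams, include_special: bool = False
):
    """Trainable augmentation of a global pooling operator.

    The vanilla pooled vector ``v`` is re-embedded as ``Q(v) + K(v) + V(v)``
    so that Cls-/Eos-/Avg-Pooling carry exactly the same number of
    trainable parameters as the attention-pooling variants built from the
    same transform architecture.
    """
    if base not in _GLOBAL_BASES:
        raise ValueError(f"unknown base operator {base!r}")
    if base == "avg":
        v = pool_avg(H, include_special).values
    else:
        v = _GLOBAL_BASES[base](H).values
    out = trainable_global_core(v, params)
    return PooledVector(out.value, f"trainable_{base}")


def trainable_global_core(v, params: PoolingParams) -> Tensor:
    """Differentiable core of :func:`trainable_global_pool`:
    ``Q(v) + K(v) + V(v)``.  Broadcasts over a leading batch axis."""
    return params.Q(v) + params.K(v) + params.V(v)


# ---------------------------------------------------------------------------
# attention pooling


def attention_weights(Hq, Hk, params: PoolingParams) -> Tensor:
    """Row-stochastic attention matrix ``softmax(Q(Hq) K(Hk)^T / scale)``.

    ``Hq`` is ``lq x d``, ``Hk`` is ``lk x d``; the result is ``lq x lk``
    with non-negative entries and unit row sums (softmax is computed with
    max-subtraction for stability).
    """
    q = as_tensor(Hq)
    k = as_tensor(Hk)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(
            f"query and key dimensions differ: {q.shape[-1]} vs {k.shape[-1]}"
        )
    scores = (params.Q(q) @ params.K(k).swapaxes(-1, -2)) / params.softmax_scale
    return softmax(scores, axis=-1)


def attention_pool_core(Xq, Xc, params: PoolingParams) -> Tensor:
    """Uniform row-average of the attention output.

    Queries come from ``Xq``; keys and values from the context ``Xc``
    (``Xc is Xq`` gives self-attention).  Supports a leading batch axis.
    """
    xq = as_tensor(Xq)
    xc = xq if Xc is Xq else as_tensor(Xc)
    attn = attention_weights(xq, xc, params)
    pooled_rows = attn @ params.V(xc)
    return pooled_rows.mean(axis=-2)


def self_attention_pool(
    H, params: PoolingParams, include_special: bool = False
) -> PooledVector:
    """Attention pooling of a single sequence: queries, keys and values all
    from ``H``; the pooled vector is the uniform average of the attention
    output rows (dimension ``d_pool``)."""
    rows = _rows(H, include_special)
    return PooledVector(attention_pool_core(rows, rows, params).value, "self_attention")


def cross_attention_pool(
    H, Hp, params: PoolingParams, include_special: bool = False
) -> PooledVector:
    """Cross-attention pooling ``P_CA(H | Hp)``: queries from ``H``, keys and
    values from the partner ``Hp``.  Asymmetric — ``P_CA(H|Hp)`` and
    ``P_CA(Hp|H)`` differ in general."""
    rows_q = _rows(H, include_special)
    rows_c = _rows(Hp, include_special)
    if rows_q.shape[1] != rows_c.shape[1]:
        raise ValueError("the two sequences must share the embedding dimension d")
    return PooledVector(
        attention_pool_core(rows_q, rows_c, params).value, "cross_attention"
    )


# ---------------------------------------------------------------------------
# windowed local pooling and BoM


def count_windows(l: int, cfg: WindowConfig) -> int:  # noqa: E741
    """Number of windows ``local_avg_pool`` emits for ``l`` tokens."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if l < cfg.k:
        return 1
    complete = (l - cfg.k) // cfg.s + 1
    covered = cfg.s * (complete - 1) + cfg.k
    return complete + (1 if cfg.tail and covered < l else 0)


def count_windows_printed_formula(l: int, cfg: WindowConfig) -> int:  # noqa: E741
    """The closed-form count ``floor((l-k+1)/s) + 1``.

    Kept for reference only: for many ``(l, k, s)`` its final window would
    read past the end of the sequence (e.g. l=10, k=3, s=1 gives 9 windows,
    the last covering positions 9..11), so the emitted bag uses
    :func:`count_windows` instead.
    """
    return (l - cfg.k + 1) // cfg.s + 1


def local_avg_pool(H, cfg: WindowConfig, include_special: bool = False) -> KmerBag:
    """Slide k-mer windows over the token rows and average within each.

    Window *i* covers 1-based positions ``s(i-1)+1 .. s(i-1)+k``; a final
    shorter tail window (if enabled) covers what the complete windows miss,
    averaged over its actual length.  A sequence shorter than ``k`` yields
    one whole-sequence window.
    """
    rows = _rows(H, include_special)
    l = rows.shape[0]  # noqa: E741
    if l < cfg.k:
        bounds = [(0, l)]
    else:
        complete = (l - cfg.k) // cfg.s + 1
        bounds = [(cfg.s * i, cfg.s * i + cfg.k) for i in range(complete)]
        covered = bounds[-1][1]
        if cfg.tail and covered < l:
            # stride-pattern start when windows overlap (s <= k); for gapped
            # configurations (s > k) start right after the covered prefix
            bounds.append((min(cfg.s * complete, covered), l))
    n = len(bounds)
    assert n == count_windows(l, cfg)
    starts = np.empty(n, dtype=int)
    lengths = np.empty(n, dtype=int)
    omegas = np.empty((n, rows.shape[1]))
    for i, (start, end) in enumerate(bounds):
        starts[i] = start + 1
        lengths[i] = end - start
        omegas[i] = rows[start:end].mean(axis=0)
    return KmerBag(omegas=omegas, starts=starts, lengths=lengths, k=cfg.k, s=cfg.s)


def bag_matrix(H, cfg: WindowConfig, include_special: bool = False) -> np.ndarray:
    """The ``n x d`` matrix of window means (shorthand for the bag's rows)."""
    return local_avg_pool(H, cfg, include_special).omegas


def bom_self_pool(
    H, cfg: WindowConfig, params: PoolingParams, include_special: bool = False
) -> PooledVector:
    """Self-attention BoM pooling: attention pooling of the k-mer bag.

    With ``k=1, s=1`` the bag equals the token matrix row-for-row, so this
    reduces bitwise to :func:`self_attention_pool`.
    """
    omegas = bag_matrix(H, cfg, include_special)
    return PooledVector(attention_pool_core(omegas, omegas, params).value, "bom_self")


def bom_cross_pool(
    H, Hp, cfg: WindowConfig, params: PoolingParams, include_special: bool = False
) -> PooledVector:
    """Cross-attention BoM pooling ``P_CBoM(H | Hp)`` over the two bags.

    A sequence shorter than ``k`` contributes a single whole-sequence
    window (the short-peptide case in domain-peptide interaction tasks).
    """
    wq = bag_matrix(H, cfg, include_special)
    wc = bag_matrix(Hp, cfg, include_special)
    if wq.shape[1] != wc.shape[1]:
        raise ValueError("the two sequences must share the embedding dimension d")
    return PooledVector(attention_pool_core(wq, wc, params).value, "bom_cross")
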