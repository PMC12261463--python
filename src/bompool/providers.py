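"""Per-residue embedding providers.

A *provider* turns an amino-acid sequence into an ``l x d`` matrix of
per-residue embeddings (one row per token), the shape of output a frozen
protein language model (PLM) encoder emits.  Two providers are offered:

* :class:`SyntheticEmbeddingProvider` — a deterministic generator used
  throughout the test-suite and the synthetic benchmarks.  Each residue
  letter has a fixed base vector (drawn once from the seed); each row is a
  mixture of its own base vector and the mean of its neighbours' base
  vectors within a context window, plus seeded Gaussian noise.  Special
  ``[Cls]``/``[EoS]`` rows with dedicated base vectors are prepended and
  appended so that Cls-/Eos-Pooling are exercisable.
* :class:`CallableProvider` — an adapter wrapping any function
  ``residues -> l x d array`` (e.g. a real PLM behind an external
  dependency); tests never require one.

Providers are deterministic: the same (sequence, provider state) always
yields bitwise-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "SequenceRecord",
    "TokenEmbeddingMatrix",
    "SyntheticEmbeddingConfig",
    "SyntheticEmbeddingProvider",
    "CallableProvider",
    "embed",
    "synthetic_embed",
]

#: The 20 standard amino acids; ``X`` marks an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = AMINO_ACIDS + "X"
_LETTER_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
_CLS_SLOT = len(_ALPHABET)
_EOS_SLOT = len(_ALPHABET) + 1


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence over the 20-letter alphabet (plus X)."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues):
            if aa not in _LETTER_INDEX:
                raise ValueError(
                    f"sequence {self.id!r} has unknown residue {aa!r} "
                    f"at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TokenEmbeddingMatrix:
    """An ``l x d`` per-residue embedding with special-token bookkeeping.

    When ``has_cls`` (``has_eos``) is set, the first (last) row holds the
    classification (end-of-sequence) token embedding rather than a residue.
    """

    values: np.ndarray
    has_cls: bool = False
    has_eos: bool = False
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("embedding matrix must be l x d with l,d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"embedding matrix for {self.source_id!r} has non-finite entries")
        if self.has_cls and self.has_eos and self.values.shape[0] < 2:
            raise ValueError("matrix too short to hold both [Cls] and [EoS] rows")

    @property
    def l(self) -> int:  # noqa: E743 - matches the field's l x d convention
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def residue_count(self) -> int:
        return self.l - int(self.has_cls) - int(self.has_eos)

    def residue_values(self) -> np.ndarray:
        """Rows covering residues only (special-token rows stripped)."""
        lo = 1 if self.has_cls else 0
        hi = self.l - 1 if self.has_eos else self.l
        return self.values[lo:hi]


@dataclass(frozen=True)
class SyntheticEmbeddingConfig:
    """Parameters of the deterministic synthetic embedding generator.

    ``mixing_weight`` is the fraction of each residue row contributed by
    its neighbours within ``context_window`` positions; ``noise_sd`` is the
    scale of seeded additive Gaussian noise.
    """

    d: int = 16
    context_window: int = 2
    mixing_weight: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not (0.0 <= self.mixing_weight < 1.0):
            raise ValueError("mixing_weight must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.context_window < 0:
            raise ValueError("context_window must be >= 0")


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Anything that maps a :class:`SequenceRecord` to embeddings."""

    has_cls: bool
    has_eos: bool
    tag: str

    def embed(self, seq: SequenceRecord) -> TokenEmbeddingMatrix: ...


class SyntheticEmbeddingProvider:
    """Deterministic residue-identity-driven embeddings with local context.

    Construction, per sequence:

    1. each residue gets the base vector of its letter (drawn once from
       ``cfg.seed``, roughly unit norm);
    2. local mixing: row *i* becomes ``(1-w) * base_i + w * mean(base_j)``
       over neighbours ``j != i`` with ``|i-j| <= context_window``;
    3. additive Gaussian noise with scale ``noise_sd``; the noise at a
       position depends only on (seed, position, letter), so substituting
       one residue perturbs only that row (when ``mixing_weight`` is 0) and
       repeated calls are bitwise identical.

    ``[Cls]``/``[EoS]`` rows use dedicated base vectors and take no part in
    mixing.
    """

    has_cls = True
    has_eos = True

    def __init__(self, cfg: SyntheticEmbeddingConfig | None = None, **kwargs):
        if cfg is None:
            cfg = SyntheticEmbeddingConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either cfg or keyword overrides, not both")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        n_slots = len(_ALPHABET) + 2  # letters + [Cls] + [EoS]
        self._base = rng.normal(0.0, 1.0, size=(n_slots, cfg.d)) / np.sqrt(cfg.d)
        # noise table indexed by (position, letter slot); grown lazily,
        # position-major so already-seen positions keep their values
        self._noise_table = np.zeros((0, n_slots, cfg.d))

    @property
    def tag(self) -> str:
        c = self.cfg
        return (
            f"synthetic-d{c.d}-w{c.context_window}-m{c.mixing_weight}"
            f"-n{c.noise_sd}-s{c.seed}"
        )

    def _noise(self, slots: np.ndarray, positions: np.ndarray) -> np.ndarray:
        max_pos = int(positions.max()) + 1
        if self._noise_table.shape[0] < max_pos:
            # regenerate from a fixed stream, position-major: a larger table
            # reproduces the smaller one in its leading positions
            n_slots = self._base.shape[0]
            rng = np.random.default_rng(np.random.SeedSequence([self.cfg.seed, 1]))
            self._noise_table = rng.normal(
                0.0, 1.0, size=(max_pos, n_slots, self.cfg.d)
            )
        return self._noise_table[positions, slots]

    def embed(self, seq: SequenceRecord) -> TokenEmbeddingMatrix:
        cfg = self.cfg
        idx = np.array([_LETTER_INDEX[a] for a in seq.residues])
        base = self._base[idx]  # (n_res, d)
        n = len(idx)
        if cfg.mixing_weight > 0 and n > 1 and cfg.context_window > 0:
            w = cfg.context_window
            # exact shifted sums (not cumsums) so rows far from an edit are
            # bitwise unaffected by it
            nb_sum = np.zeros_like(base)
            counts = np.zeros(n)
            for off in range(1, w + 1):
                nb_sum[off:] += base[:-off]
                counts[off:] += 1
                nb_sum[:-off] += base[off:]
                counts[:-off] += 1
            mixed = base.copy()
            has_nb = counts > 0
            mixed[has_nb] = (1 - cfg.mixing_weight) * base[has_nb] + (
                cfg.mixing_weight * nb_sum[has_nb] / counts[has_nb, None]
            )
        else:
            mixed = base
        slots = np.concatenate([[_CLS_SLOT], idx, [_EOS_SLOT]])
        rows = np.vstack([self._base[_CLS_SLOT], mixed, self._base[_EOS_SLOT]])
        if cfg.noise_sd > 0:
            positions = np.arange(n + 2)
            rows = rows + cfg.noise_sd * self._noise(slots, positions)
        return TokenEmbeddingMatrix(rows, has_cls=True, has_eos=True, source_id=seq.id)


class CallableProvider:
    """Adapter exposing any ``residues -> l x d array`` function as a provider.

    This is the hook for real frozen-PLM backends (ESM, ProtT5, ...): wrap
    the model's forward pass in a function and declare whether it emits
    special-token rows.
    """

    def __init__(
        self,
        fn: Callable[[str], np.ndarray],
        has_cls: bool = False,
        has_eos: bool = False,
        tag: str = "callable",
    ):
        self._fn = fn
        self.has_cls = has_cls
        self.has_eos = has_eos
        self.tag = tag

    def embed(self, seq: SequenceRecord) -> TokenEmbeddingMatrix:
        values = np.asarray(self._fn(seq.residues), dtype=np.float64)
        return TokenEmbeddingMatrix(
            values, has_cls=self.has_cls, has_eos=self.has_eos, source_id=seq.id
        )


def synthetic_embed(
    seq: SequenceRecord, cfg: SyntheticEmbeddingConfig | None = None
) -> TokenEmbeddingMatrix:
    """One-shot synthetic embedding of a single sequence.

    Convenience wrapper constructing a :class:`SyntheticEmbeddingProvider`
    from ``cfg``; for batches, build the provider once and reuse it (the
    noise table is cached per provider).
    """
    return embed(seq, SyntheticEmbeddingProvider(cfg))


def embed(seq: SequenceRecord, provider: EmbeddingProvider) -> TokenEmbeddingMatrix:
    """Embed one sequence through ``provider`` (validates the record first)."""
    if not isinstance(seq, SequenceRecord):
        seq = SequenceRecord(*seq)
    mat = provider.embed(seq)
    expected = len(seq) + int(provider.has_cls) + int(provider.has_eos)
    if mat.l != expected:
        raise ValueError(
            f"provider {provider.tag!r} returned {mat.l} rows for "
            f"{seq.id!r}; expected {expected}"
        )
    return mat
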