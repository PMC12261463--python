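"""Representation-level similarity diagnostics.

Two training-free probes of what a pooled representation can and cannot
distinguish:

* :func:`cosine_heatmap` — the full matrix of pairwise cosine
  similarities among a set of pooled vectors (e.g. Avg- vs Cls-pooled
  representations of proteins from different structural folds);
* :func:`min_local_cosine` — a windowed measure for near-identical
  variants: average-pool every stride-1 k-mer of each sequence, greedily
  align each k-mer of one sequence to its best-matching k-mer in the
  other, and report the *minimum* of those best-match similarities — the
  least similar match in the embedding-space alignment.  Point mutations
  that barely move a global average show up sharply here.

The windowed measure is directional; :func:`min_local_cosine_symmetric`
reports both directions and their minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pooling import WindowConfig, local_avg_pool

__all__ = [
    "SimilarityMatrix",
    "cosine_heatmap",
    "min_local_cosine",
    "min_local_cosine_symmetric",
]


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of cosine similarities with row/column ids."""

    ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _unit_rows(mat: np.ndarray, ids=None) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        name = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise ValueError(f"zero-norm representation for {name}")
    return mat / norms[:, None]


def cosine_heatmap(reps: dict[str, np.ndarray]) -> SimilarityMatrix:
    """Pairwise cosine similarities among pooled representations.

    ``reps`` maps sequence ids to equal-dimension vectors; the result is a
    symmetric matrix with unit diagonal.
    """
    if len(reps) < 2:
        raise ValueError("need at least two representations")
    ids = list(reps)
    mat = np.vstack([np.asarray(reps[i], dtype=float).ravel() for i in ids])
    unit = _unit_rows(mat, ids)
    values = unit @ unit.T
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, np.clip(values, -1.0, 1.0))


def _kmer_means(H, k: int) -> np.ndarray:
    """All stride-1 k-mer averages of the token rows (one window if l < k)."""
    return local_avg_pool(H, WindowConfig(k=k, s=1, tail=False)).omegas


def min_local_cosine(Ha, Hb, k: int = 7) -> float:
    """Minimum best-match cosine similarity of Ha's k-mers against Hb's.

    For each k-mer average of ``Ha``, take the maximum cosine similarity
    over all k-mer averages of ``Hb``; return the minimum of these maxima.
    Directional: swapping the arguments can change the value when the
    sequences differ in length or content.
    """
    a = _unit_rows(_kmer_means(Ha, k))
    b = _unit_rows(_kmer_means(Hb, k))
    sims = a @ b.T
    return float(sims.max(axis=1).min())


def min_local_cosine_symmetric(Ha, Hb, k: int = 7) -> dict[str, float]:
    """Both directions of :func:`min_local_cosine` plus their minimum."""
    ab = min_local_cosine(Ha, Hb, k)
    ba = min_local_cosine(Hb, Ha, k)
    return {"a_to_b": ab, "b_to_a": ba, "min": min(ab, ba)}
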