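"""Task metrics and pairwise evaluation protocols.

* :func:`spearman` — tie-adjusted rank correlation for the regression
  tasks (undefined on constant inputs, reported as NaN rather than 0);
* :func:`pair_likelihood` — the homology/interaction score of a pair,
  the negative cosine distance of the two pooled representations; for
  cross-attention BoM pooling the two representations are pair-dependent
  (each sequence re-pooled against the other), which makes the score
  symmetric in its arguments;
* :func:`per_sequence_auroc` — the remote-homology protocol: for one
  query, AUROC over its partners with remote-homolog pairs positive,
  nonhomolog pairs negative, and nonremote-homolog pairs excluded;
* :func:`interaction_auroc` — pooled AUROC over all domain-peptide pairs.

AUROC is the Mann-Whitney statistic (ties contribute one half), computed
through scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .heads import cosine_distance
from .pooling import (
    PoolingParams,
    WindowConfig,
    bom_cross_pool,
    bom_self_pool,
    pool_avg,
    pool_cls,
    pool_eos,
    self_attention_pool,
)

__all__ = [
    "EvalPairSet",
    "spearman",
    "pair_likelihood",
    "per_sequence_auroc",
    "per_sequence_auroc_report",
    "interaction_auroc",
]

logger = logging.getLogger(__name__)

_HOMOLOGY_VOCAB = {"remote_homolog", "nonremote_homolog", "nonhomolog"}
_INTERACTION_VOCAB = {"interacting", "noninteracting"}


@dataclass
class EvalPairSet:
    """Labeled unordered sequence pairs with category labels."""

    pairs: pd.DataFrame  # columns: id_a, id_b, category

    def __post_init__(self):
        df = self.pairs
        missing = {"id_a", "id_b", "category"} - set(df.columns)
        if missing:
            raise ValueError(f"pair table lacks columns {sorted(missing)}")
        cats = set(df["category"].unique())
        if not (cats <= _HOMOLOGY_VOCAB or cats <= _INTERACTION_VOCAB):
            raise ValueError(f"categories {sorted(cats)} outside the known vocabularies")
        keys = df.apply(lambda r: frozenset((r["id_a"], r["id_b"])), axis=1)
        if keys.duplicated().any():
            raise ValueError("duplicate unordered pairs in the table")

    def partners_of(self, query_id: str) -> pd.DataFrame:
        df = self.pairs
        mask = (df["id_a"] == query_id) | (df["id_b"] == query_id)
        sub = df[mask].copy()
        sub["partner"] = np.where(sub["id_a"] == query_id, sub["id_b"], sub["id_a"])
        return sub


def spearman(preds, targets) -> float:
    """Spearman's rank correlation with average ranks for ties.

    Returns NaN when either vector is constant (the correlation is then
    undefined; callers should treat it as missing, not as zero).
    """
    p = np.asarray(preds, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("spearman needs two equal-length vectors of length >= 2")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        logger.warning("spearman undefined on constant input; returning NaN")
        return float("nan")
    return float(stats.spearmanr(p, t).statistic)


def pair_likelihood(
    Ha,
    Hb,
    method: str = "avg",
    params: PoolingParams | None = None,
    window: WindowConfig | None = None,
) -> float:
    """Likelihood that two sequences are related: minus their pooled
    cosine distance.

    ``method`` selects the pooling operator (``cls``, ``eos``, ``avg``,
    ``self_attention``, ``bom_self``, ``bom_cross``).  For ``bom_cross``
    the score is ``-Δ(P_CBoM(Ha|Hb), P_CBoM(Hb|Ha))``; cosine distance is
    symmetric, so the score does not depend on argument order.
    """
    if method == "avg":
        ra, rb = pool_avg(Ha).values, pool_avg(Hb).values
    elif method == "cls":
        ra, rb = pool_cls(Ha).values, pool_cls(Hb).values
    elif method == "eos":
        ra, rb = pool_eos(Ha).values, pool_eos(Hb).values
    elif method == "self_attention":
        ra = self_attention_pool(Ha, params).values
        rb = self_attention_pool(Hb, params).values
    elif method == "bom_self":
        ra = bom_self_pool(Ha, window, params).values
        rb = bom_self_pool(Hb, window, params).values
    elif method == "bom_cross":
        ra = bom_cross_pool(Ha, Hb, window, params).values
        rb = bom_cross_pool(Hb, Ha, window, params).values
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return float(-cosine_distance(ra, rb).value)


def _auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    return float(roc_auc_score(labels, scores))


def per_sequence_auroc(query_id: str, pairs: EvalPairSet, likelihoods: dict) -> float:
    """Per-query remote-homology AUROC.

    ``likelihoods`` maps unordered id pairs (any order, or frozensets) to
    scores.  Remote-homolog partners are positives, nonhomolog partners
    negatives; nonremote-homolog partners are excluded from the ranking.
    """
    sub = pairs.partners_of(query_id)
    sub = sub[sub["category"] != "nonremote_homolog"]
    if sub.empty:
        raise ValueError(f"query {query_id!r} has no scoreable partners")
    labels = (sub["category"] == "remote_homolog").to_numpy()
    if labels.all() or not labels.any():
        raise ValueError(
            f"query {query_id!r} lacks a positive or negative partner after exclusions"
        )
    scores = np.array([_lookup(likelihoods, query_id, p) for p in sub["partner"]])
    return _auroc(labels, scores)


def _lookup(likelihoods: dict, a: str, b: str) -> float:
    for key in ((a, b), (b, a), frozenset((a, b))):
        if key in likelihoods:
            return float(likelihoods[key])
    raise KeyError(f"no likelihood recorded for pair ({a}, {b})")


def per_sequence_auroc_report(pairs: EvalPairSet, likelihoods: dict) -> pd.DataFrame:
    """AUROC for every query appearing in the pair table.

    Queries without both a positive and a negative partner after the
    nonremote-homolog exclusion are skipped with a logged reason; the
    result has one row per scored query.
    """
    ids = sorted(set(pairs.pairs["id_a"]) | set(pairs.pairs["id_b"]))
    rows = []
    for qid in ids:
        try:
            rows.append({"id": qid, "auroc": per_sequence_auroc(qid, pairs, likelihoods)})
        except ValueError as exc:
            logger.info("skipping query %s: %s", qid, exc)
    return pd.DataFrame(rows)


def interaction_auroc(pairs, likelihoods: dict | None = None) -> float:
    """Pooled AUROC over all domain-peptide pairs.

    ``pairs`` may be an :class:`EvalPairSet` with interacting /
    noninteracting categories (scores from ``likelihoods``), or a
    DataFrame with boolean ``interacting`` and float ``likelihood``
    columns.
    """
    if isinstance(pairs, EvalPairSet):
        df = pairs.pairs
        labels = (df["category"] == "interacting").to_numpy()
        scores = np.array(
            [_lookup(likelihoods, a, b) for a, b in zip(df["id_a"], df["id_b"])]
        )
    else:
        labels = pairs["interacting"].to_numpy(dtype=bool)
        scores = pairs["likelihood"].to_numpy(dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("interaction AUROC needs both classes present")
    return _auroc(labels, scores)
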