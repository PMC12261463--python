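"""End-to-end synthetic benchmarks for comparing pooling strategies.

Each function builds its dataset from the synthetic generators, embeds it
with the deterministic provider, trains the relevant estimator(s) and
returns the task metric.  Everything is a pure function of the ``seed``
argument, so results are exactly reproducible; these are the computations
behind the package's reported numbers (see ``scripts/acceptance.py``).
"""

from __future__ import annotations

import numpy as np

import bompool as bp
from .estimators import (
    ContrastiveHomologyEmbedder,
    CrossAttentionInteractionModel,
    PooledEmbeddingRegressor,
    assert_parameter_parity,
)
from .evaluation import EvalPairSet, interaction_auroc, per_sequence_auroc_report, spearman
from .heads import cosine_distance
from .synthetic import (
    HierarchySpec,
    InteractionSpec,
    MotifRegressionSpec,
    make_homology_dataset,
    make_interaction_dataset,
    make_regression_dataset,
)

__all__ = [
    "REGRESSION_TRAIN_SETTINGS",
    "regression_benchmark",
    "homology_benchmark",
    "interaction_benchmark",
]

#: Shared training settings for the regression comparison.  Identical
#: across pooling methods (same transform architecture, same epoch budget)
#: so that the comparison is parameter- and budget-fair.
REGRESSION_TRAIN_SETTINGS = dict(
    d_pool=16,
    hidden=(16,),
    epochs=1200,
    lr=0.02,
    lr_schedule="cosine",
    weight_decay=1e-3,
    batch_size=100,
    patience=None,
)

#: Window setting used by BoM pooling in the regression benchmark: with
#: k=5 and stride 2 every planted 6-mer is mostly contained in some window.
REGRESSION_WINDOW = dict(k=5, s=2)


def _embed_all(records, provider=None):
    provider = provider or bp.SyntheticEmbeddingProvider()
    return {r.id: bp.embed(r, provider) for r in records}


def regression_benchmark(
    seed: int,
    methods: tuple[str, ...] = ("bom", "attention", "avg"),
    n_seeds: int = 5,
) -> dict[str, list[float]]:
    """Validation Spearman of pooling methods on the planted-motif task.

    One dataset (two planted motifs, interaction-bearing labels) is drawn
    from ``seed``; each method is trained ``n_seeds`` times with training
    seeds derived from ``seed``.  All methods share the same transform
    architecture and training budget, and their trainable pooling
    parameter counts are asserted equal before any run.
    """
    assert_parameter_parity(
        methods,
        d=bp.SyntheticEmbeddingConfig().d,
        d_pool=REGRESSION_TRAIN_SETTINGS["d_pool"],
        hidden=REGRESSION_TRAIN_SETTINGS["hidden"],
    )
    ds = make_regression_dataset(MotifRegressionSpec(motif2="TPRQGN", seed=seed))
    emb = _embed_all(ds.records)
    X = [emb[r.id] for r in ds.records]
    y, tr, va = ds.labels, ds.splits["train"], ds.splits["valid"]
    Xtr = [X[i] for i in tr]
    Xva = [X[i] for i in va]
    train_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_seeds) % 2**31]
    results: dict[str, list[float]] = {}
    for method in methods:
        window = REGRESSION_WINDOW if method == "bom" else {}
        rhos = []
        for ts in train_seeds:
            est = PooledEmbeddingRegressor(
                pooling=method, random_state=ts, **REGRESSION_TRAIN_SETTINGS, **window
            )
            est.fit(Xtr, y[tr], X_val=Xva, y_val=y[va])
            rhos.append(spearman(est.predict(Xva), y[va]))
        results[method] = rhos
    return results


def homology_benchmark(seed: int, pooling: str = "bom") -> dict:
    """Median per-sequence remote-homology AUROC after contrastive training.

    One member per family is held out; training triplets use superfamily
    labels of the remaining members.  Evaluation scores all held-out pairs
    with the negative cosine distance of the trained representations and
    applies the remote-homology protocol (nonremote-homolog pairs
    excluded).
    """
    ds = make_homology_dataset(HierarchySpec(seed=seed))
    emb = _embed_all(ds.records)
    holdout_member = HierarchySpec().members_per_family - 1
    test_ids = [r.id for r in ds.records if r.id.endswith(f"_m{holdout_member}")]
    train_ids = [r.id for r in ds.records if r.id not in set(test_ids)]
    lineage = ds.lineage.set_index("id")
    est = ContrastiveHomologyEmbedder(
        pooling=pooling, k=5, s=2, d_pool=16, hidden=(16,),
        epochs=200, random_state=seed,
    )
    est.fit([emb[i] for i in train_ids], [lineage.loc[i, "superfamily"] for i in train_ids])
    reps = dict(zip(test_ids, est.transform([emb[i] for i in test_ids])))
    pairs = ds.pairs[
        ds.pairs["id_a"].isin(test_ids) & ds.pairs["id_b"].isin(test_ids)
    ].reset_index(drop=True)
    likelihoods = {
        (a, b): -float(cosine_distance(reps[a], reps[b]).value)
        for a, b in zip(pairs["id_a"], pairs["id_b"])
    }
    report = per_sequence_auroc_report(EvalPairSet(pairs), likelihoods)
    return {
        "median_auroc": float(report["auroc"].median()),
        "q1": float(report["auroc"].quantile(0.25)),
        "q3": float(report["auroc"].quantile(0.75)),
        "n_queries": int(len(report)),
        "report": report,
    }


def interaction_benchmark(seed: int) -> dict:
    """Domain-peptide interaction AUROC with cross-attention BoM pooling.

    Noise-free compatibility rule; triplets pair each domain anchor with
    an interacting and a non-interacting peptide.  The reported AUROC
    pools all domain-peptide pairs scored with the pair-dependent
    representations.
    """
    ds = make_interaction_dataset(InteractionSpec(seed=seed))
    provider = bp.SyntheticEmbeddingProvider()
    demb = _embed_all(ds.domains, provider)
    pemb = _embed_all(ds.peptides, provider)
    est = CrossAttentionInteractionModel(
        k=30, s=10, d_pool=16, hidden=(16,), epochs=150, random_state=seed
    )
    est.fit(demb, pemb, ds.interactions)
    scored = est.score_pairs(ds.interactions)
    return {"auroc": float(interaction_auroc(scored)), "scored": scored}
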