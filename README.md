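# bompool

Locality-aware pooling for protein language model (PLM) embeddings.

PLMs emit one contextual embedding per residue, so a protein of length
*l* becomes an *l×d* matrix **H**. Sequence-level prediction needs a
fixed-size vector, and the usual reductions — Cls-Pooling (**h**₁),
Eos-Pooling (**h**ₗ) and Avg-Pooling (mean of rows) — are blind to the
short motifs and motif-motif interactions that often determine protein
behaviour. `bompool` implements:

* **attention pooling** — the uniform row-average of
  `softmax(Q(H)K(H)ᵀ/√d_pool)V(H)`, with learnable Q/K/V transforms
  (self- and cross-sequence variants);
* **BoM-Pooling** (bag-of-mer pooling) — windowed local averaging over
  sliding k-mers (window *k*, stride *s*) followed by attention pooling
  over the window bag, shrinking the attention matrix from *l*² to
  *n(l,s,k)*² entries while retaining locality;
* trainable-augmented global pooling (`Q(v)+K(v)+V(v)`) so every method
  in a comparison has the same number of trainable parameters;
* downstream machinery: a 3-layer regression head (jointly optimized
  with the pooling transforms against MSE), cosine-distance triplet
  learning for homology detection, and pair-dependent cross-attention
  BoM training for domain–peptide interaction prediction;
* evaluation protocols (tie-aware Spearman ρ, per-sequence
  remote-homology AUROC with nonremote-homolog exclusion, pooled
  interaction AUROC) and diagnostics (cosine-similarity heatmaps,
  minimum-local-cosine alignment measure, fidelity–compactness sweeps);
* seeded synthetic generators (planted-motif regression, a
  fold/superfamily/family homology hierarchy, motif-compatibility
  domain–peptide interactions) so the whole pipeline runs without
  downloads, plus an adapter interface for real frozen PLMs.

See `docs/methods.md` for the model details and the synthetic-data
assumptions.

## Worked example

Train BoM-Pooling and parameter-matched trainable Avg-Pooling on a
planted-motif regression task whose labels depend on two motifs and
their interaction:

```python
import numpy as np
import bompool as bp
from bompool.synthetic import MotifRegressionSpec, make_regression_dataset
from bompool.evaluation import spearman

ds = make_regression_dataset(MotifRegressionSpec(motif2="TPRQGN", seed=0))
provider = bp.SyntheticEmbeddingProvider()
X = [bp.embed(r, provider) for r in ds.records]
y, tr, va = ds.labels, ds.splits["train"], ds.splits["valid"]

for pooling in ["bom", "avg"]:
    est = bp.PooledEmbeddingRegressor(
        pooling=pooling, k=5, s=2, d_pool=16, hidden=(16,),
        epochs=1200, lr=0.02, lr_schedule="cosine", weight_decay=1e-3,
        patience=None, random_state=1,
    )
    est.fit([X[i] for i in tr], y[tr],
            X_val=[X[i] for i in va], y_val=y[va])
    rho = spearman(est.predict([X[i] for i in va]), y[va])
    print(f"{pooling:4s}  validation Spearman rho = {rho:.3f}")
```

Output:

```
bom   validation Spearman rho = 0.796
avg   validation Spearman rho = 0.482
```

Both models carry identical trainable-parameter counts (asserted by
`bompool.assert_parameter_parity`); the gap is the value of locality: a
6-residue motif barely moves a 60-residue average, but it dominates some
sliding window, and attention over the window bag learns to focus there.
Window choice is itself diagnosable — `bompool.fidelity.fidelity_sweep`
tabulates how faithfully each (k, s) preserves the token embeddings.

A command-line interface mirrors the library
(`bompool embed | train-regression | train-contrastive | eval-pairs |
fidelity | similarity`); every subcommand takes `--seed` and echoes its
configuration into the output directory.

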