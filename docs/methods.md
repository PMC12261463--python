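# Methods

## Problem setting

Protein language models (PLMs) emit one contextual embedding vector per
residue: a sequence of length `l` becomes an `l x d` matrix `H` (usually
with a `[Cls]` row prepended and an `[EoS]` row appended). Sequence-level
prediction needs a fixed-size vector, so `H` is *pooled*. The classical
choices — the `[Cls]` row, the `[EoS]` row, or the mean of all rows — are
global reductions that cannot single out the short motifs and long-range
motif interactions that often drive protein behaviour. This package
implements locality-aware alternatives and the machinery to compare all of
them end to end.

## Pooling operators

Let `H = [h_1 .. h_l]` with rows in `R^d`.

* **Global pooling**: `P_CLS = h_1`, `P_EoS = h_l`, `P_Avg = (1/l) Σ h_i`.
  By default the `[Cls]`/`[EoS]` rows are excluded from averages and
  windows (flag to include); windows should cover residues.
* **Trainable global pooling**: `Q(v) + K(v) + V(v)` where `v` is the
  vanilla pooled vector and `Q, K, V` are the same transform triple used
  by the attention operators — so every method in a comparison carries an
  identical trainable-parameter count (asserted programmatically before
  any paired run).
* **Self-attention pooling**:
  `P_SA(H) = (1/l) 1^T softmax(Q(H) K(H)^T / sqrt(d_pool)) V(H)` —
  the uniform row-average of the attention output. With constant `Q, K`
  and identity `V` this reduces exactly to `P_Avg`. Note that this
  operator is invariant to permuting the rows of `H` (row-softmax is
  permutation-equivariant and the final average is symmetric); position
  sensitivity enters only through the windowing below.
* **Cross-attention pooling**:
  `P_CA(H | H') = (1/l) 1^T softmax(Q(H) K(H')^T / sqrt(d_pool)) V(H')`,
  asymmetric in its two arguments.
* **Windowed local averaging**: sliding k-mers with stride `s`; window `i`
  covers 1-based positions `s(i-1)+1 .. s(i-1)+k` and is reduced to its
  mean `ω_i`. The bag holds all `⌊(l-k)/s⌋ + 1` complete windows plus, by
  default, one shorter tail window covering the residues after the last
  complete window (for gapped settings `s > k` the tail starts right
  after the covered prefix). A sequence shorter than `k` contributes one
  whole-sequence window. A closed-form count that instead emits
  `⌊(l-k+1)/s⌋ + 1` windows is kept for reference
  (`count_windows_printed_formula`) but is not used to build bags: for
  many `(l, k, s)` its final window would read past the end of the
  sequence.
* **BoM (bag-of-mer) pooling**: attention pooling applied to the k-mer
  bag instead of the raw tokens. The attention matrix shrinks from `l^2`
  to `n(l,s,k)^2` entries; with `k = s = 1` the bag is `H` itself and BoM
  pooling is bitwise-identical to full attention pooling.

`Q, K, V` are unshared one-hidden-layer MLPs `d -> hidden -> d_pool`
(default `hidden = (d_pool,)`, tanh). Architecture (depth, width,
activation) is configurable; tanh is the default so that finite-difference
gradient checks are meaningful everywhere. The softmax denominator is
`sqrt(d_pool)` — the dimension of the query/key product space — and
softmax uses max-subtraction. All arithmetic is float64.

## Heads and objectives

* **Regression**: a 3-layer feed-forward head `d_pool -> 256 -> 64 -> 1`
  with batch normalization and dropout 0.3 between layers (batch-norm
  before the activation; per-batch statistics in train mode, running
  averages in eval mode; train mode therefore needs batches of at least
  2). Pooling transforms and head are optimized jointly against MSE.
* **Contrastive**: triplet loss `max(0, Δ(a,p) - Δ(a,n) + m)` with cosine
  distance `Δ(u,v) = 1 - u·v/(‖u‖‖v‖)` and margin `m = 0.6`. Norms carry
  an epsilon of 1e-12 after an explicit zero-norm rejection at tolerance
  1e-9. For cross-attention BoM the distances are pair-dependent:
  `Δ(P_CBoM(Ha|Hp), P_CBoM(Hp|Ha))` — each member of a pair is re-pooled
  against the other. Cosine distance is symmetric, so the resulting pair
  score does not depend on argument order.
* **Optimization**: Adam (first-order, adaptive moments) over all
  parameters, driven by a small reverse-mode automatic-differentiation
  engine on numpy arrays written for this package (`bompool.autodiff`);
  gradient correctness is enforced by finite-difference tests at 1e-4.
  Optional cosine learning-rate decay (to lr/20 over the epoch budget)
  and decoupled weight decay. The output layer of the Q transform is
  initialized at zero, so attention starts exactly uniform: the value
  pathway first learns set-average window detectors and attention
  sharpens only as the loss demands it, which avoids a failure mode
  where attention locks onto the strongest single pattern early and
  weaker planted determinants are memorized around rather than detected
  (Q stays trainable — its gradient flows through K's features).
  Training is a pure function of (data, config, seed): parameter
  initialization, batch order, dropout masks and triplet draws all derive
  from one seed sequence. Early stopping tracks validation MSE with
  configurable patience and restores the best snapshot.

## Evaluation protocols

* **Spearman's ρ** with average ranks for ties (undefined on constant
  vectors — reported as NaN, never coerced to 0).
* **Per-sequence remote-homology AUROC**: for each query, its partners
  are ranked by likelihood `-Δ` of the pooled representations;
  remote-homolog pairs (same superfamily, different family) are
  positives, nonhomolog pairs negatives, and nonremote-homolog pairs
  (same family) are excluded. Queries lacking both classes are skipped
  with a logged reason; the distribution of per-query AUROCs is reported
  (median annotated). AUROC is the Mann-Whitney statistic; ties count
  one half.
* **Interaction AUROC**: pooled over all domain-peptide pairs.

## Fidelity-compactness diagnostic

For a window setting `(k, s)`, *compactness* is `n/l` (windows per
original token) and *fidelity error* is the mean squared Euclidean
deviation between each token embedding and its representative — the mean
of the pooled vectors of all windows covering that token. This is the
package's operational definition of pooling fidelity: it is zero at
`k = s = 1`, equals the total variance of the rows about the global mean
for a single whole-sequence window, and is zero for any block-constant
embedding whose blocks align with the windows (`k = s =` block length).
The error is driven by within-window variance, which the report also
aggregates per window.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a seeded spec and produce desk-scale
datasets with the statistical structure each task family assumes.

**Embeddings.** Each residue letter has a fixed base vector of roughly
unit norm (per-component scale `1/sqrt(d)`, `d = 16` by default). Row `i`
is `(1-w)·base_i + w·mean(base_j)` over neighbours within ±2 positions,
with mixing weight `w = 0.5` — PLM embeddings are strongly
context-driven, and it is precisely this context that makes local motifs
visible to attention at the token level. Additive Gaussian noise
(`sd = 0.05` per component, ~17% of the embedding norm) depends only on
(seed, position, letter), so embedding is fully deterministic and a
single substitution perturbs exactly one row when mixing is off.
Dedicated `[Cls]`/`[EoS]` base vectors make Cls-/Eos-Pooling exercisable.
What this does *not* emulate: attention-driven long-range context,
tokenizer quirks, or the anisotropic geometry of real PLM embedding
spaces — passing tests show the operators and training loops behave as
specified, not that any particular PLM will benefit on a given real task.

**Regression (planted motifs).** 500 random-background sequences of
length 60; motif `WYWHCK` and optionally `TPRQGN` are each planted with
probability 1/2 at non-overlapping uniform positions. Labels:
`2·I1 + 4·I2 + 3·I1·I2` plus Gaussian noise (sd 0.5). The distinct main
effects give four distinct label levels (Spearman against a noisy
continuum is otherwise capped near 0.84 by rank ties among equal label
groups); an interaction term is present so that methods that can
represent motif co-occurrence have an advantage. Motif length 6 exceeds
the context half-width 2, so interior motif tokens carry clean all-motif
context signatures. Global averaging is genuinely handicapped here for
the scientific reason the operators exist: a 6-residue motif shifts the
60-residue composition by less than the binomial composition noise of
the random background.

**Homology hierarchy.** A common ancestor is mutated down a
fold -> superfamily -> family tree (i.i.d. substitutions, uniform over
the 19 alternatives — the simplest model with the right identity
ordering, with no claim of biological realism). Branch rates are set so
expected pairwise divergences match the spec: 0.05 within families, 0.20
between families of one superfamily (remote homologs), ≥0.60 across
superfamilies/folds. Default 3 folds x 2 superfamilies x 2 families x 4
members, length 60.

**Domain-peptide interactions.** Three domain classes, each with a
length-6 signature motif planted inside its domains (lengths 80-120);
twelve length-9 peptides each carry one class motif. A peptide interacts
with a domain iff it carries the domain's class motif — a hidden
compatibility rule that is learnable from sequence, with an optional
label-noise rate (default noise-free). Domains are windowed (default
`k=30, s=10`); peptides are shorter than `k` and contribute a single
whole-sequence window, so cross-attention aligns the peptide against
domain windows.

## Problem sizes and numerical choices

The benchmark experiments shipped with the package (test suite and
`scripts/acceptance.py`) use the dataset sizes above with pooled
dimensions `d_pool = 16`, `hidden = (16,)`; the regression comparison
trains every method for 1200 Adam epochs (lr 0.02, cosine decay, weight
decay 1e-3) with five training seeds per method, and the contrastive
tasks use 150-200 epochs — sizes chosen so a full run completes in
minutes on one CPU core while keeping the paired pooling comparisons
parameter- and budget-matched. Ties in AUROC are handled by
the Mann-Whitney convention; degenerate inputs (empty selections,
zero-norm vectors, starved anchors, constant metric inputs) raise or are
skipped with logged reasons rather than silently coerced.

## Known limitations

* The synthetic embedding generator's context is a fixed local mixture;
  it cannot test whether attention pooling exploits *learned* long-range
  PLM context.
* The fidelity metric is this package's operational definition (token vs
  mean-of-covering-windows); other formalizations of "fidelity" exist.
* Multi-head attention and positional encodings inside the pooling layer
  are out of scope, as is replacing PLM-internal layers (BoM reduces the
  output dimension of the layer it is applied to).
* The real-PLM provider is an adapter interface (`CallableProvider`);
  no pretrained weights are bundled or downloaded.
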