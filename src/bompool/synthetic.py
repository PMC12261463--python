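"""Synthetic benchmark datasets with planted statistical structure.

Desk-scale generators that emulate the structure of the three task
families the pooling operators target, so every pipeline stage is testable
without external downloads:

* :func:`make_regression_dataset` — sequences whose real-valued label is
  driven by one planted motif, or by the *interaction* of two motifs
  (label shifts only when both are present), emulating fitness landscapes
  dominated by a few local determinants;
* :func:`make_homology_dataset` — a fold -> superfamily -> family
  hierarchy produced by mutating a common ancestor down a tree, with pair
  labels remote_homolog (same superfamily, different family),
  nonremote_homolog (same family) and nonhomolog (different superfamily);
* :func:`make_interaction_dataset` — binding domains and short peptides
  whose interaction is decided by a hidden class -> motif compatibility
  rule (the class signature motif is planted inside the domain, so the
  rule is learnable from sequence).

All generators are pure functions of their spec (seeded); substitutions
are i.i.d. per site, uniform over the 19 alternative residues — the
simplest model realizing the required identity orderings, with no claim of
biological realism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .providers import AMINO_ACIDS, SequenceRecord

__all__ = [
    "MotifRegressionSpec",
    "HierarchySpec",
    "InteractionSpec",
    "RegressionDataset",
    "HomologyDataset",
    "InteractionDataset",
    "make_regression_dataset",
    "make_homology_dataset",
    "make_interaction_dataset",
]

_AA = np.array(list(AMINO_ACIDS))


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """I.i.d. substitutions at per-site probability ``rate``."""
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [a for a in AMINO_ACIDS if a != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of matching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequence_identity needs equal-length sequences")
    return float(np.mean(np.array(list(a)) == np.array(list(b))))


# ---------------------------------------------------------------------------
# regression task


@dataclass(frozen=True)
class MotifRegressionSpec:
    """Planted-motif regression task.

    With ``motif2`` unset, labels are ``baseline + effect_size * I(motif)``
    plus Gaussian noise.  With ``motif2`` set, labels are
    ``baseline + m1*I1 + m2*I2 + effect_size * I1*I2`` with per-motif main
    effects ``(m1, m2) = main_effect``: distinct main effects give four
    distinct label levels, as in mutational-scanning data where sites
    contribute unequally.  Setting ``main_effect=(0, 0)`` yields a pure
    interaction: sequences with exactly one motif carry the baseline.
    """

    n_sequences: int = 500
    length: int = 60
    motif: str = "WYWHCK"
    motif2: str | None = None
    effect_size: float = 3.0
    main_effect: tuple[float, float] = (2.0, 4.0)
    baseline: float = 0.0
    motif_prob: float = 0.5
    label_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        need = len(self.motif) + (len(self.motif2) if self.motif2 else 0)
        if need >= self.length:
            raise ValueError("motifs do not fit in the sequence length")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.label_noise_sd < 0:
            raise ValueError("label_noise_sd must be >= 0")


@dataclass
class RegressionDataset:
    records: list[SequenceRecord]
    labels: np.ndarray
    motif_present: np.ndarray  # (n,) or (n, 2) indicator(s)
    splits: dict[str, np.ndarray]  # train/valid/test index arrays
    spec: MotifRegressionSpec


def _plant(arr: np.ndarray, motif: str, rng: np.random.Generator, occupied: set[int]):
    """Overwrite a random free stretch with ``motif``; returns positions used."""
    m = len(motif)
    candidates = [
        p
        for p in range(arr.size - m + 1)
        if not any(q in occupied for q in range(p, p + m))
    ]
    if not candidates:
        raise ValueError("no non-overlapping placement available for motif")
    p = candidates[rng.integers(len(candidates))]
    arr[p : p + m] = list(motif)
    occupied.update(range(p, p + m))
    return p


def make_regression_dataset(spec: MotifRegressionSpec) -> RegressionDataset:
    """Generate sequences, labels and a 70/15/15 train/valid/test split."""
    rng = np.random.default_rng(spec.seed)
    records, indicators = [], []
    for i in range(spec.n_sequences):
        arr = np.array(list(_random_sequence(spec.length, rng)))
        occupied: set[int] = set()
        has1 = rng.random() < spec.motif_prob
        if has1:
            _plant(arr, spec.motif, rng, occupied)
        if spec.motif2 is not None:
            has2 = rng.random() < spec.motif_prob
            if has2:
                _plant(arr, spec.motif2, rng, occupied)
            indicators.append((float(has1), float(has2)))
        else:
            indicators.append(float(has1))
        records.append(SequenceRecord(f"seq{i:04d}", "".join(arr)))
    ind = np.asarray(indicators)
    if spec.motif2 is None:
        signal = spec.effect_size * ind
    else:
        m1, m2 = (
            spec.main_effect
            if isinstance(spec.main_effect, (tuple, list))
            else (spec.main_effect, spec.main_effect)
        )
        signal = (
            m1 * ind[:, 0]
            + m2 * ind[:, 1]
            + spec.effect_size * ind[:, 0] * ind[:, 1]
        )
    labels = spec.baseline + signal + spec.label_noise_sd * rng.normal(
        size=spec.n_sequences
    )
    perm = rng.permutation(spec.n_sequences)
    n_train = int(round(0.7 * spec.n_sequences))
    n_valid = int(round(0.15 * spec.n_sequences))
    splits = {
        "train": np.sort(perm[:n_train]),
        "valid": np.sort(perm[n_train : n_train + n_valid]),
        "test": np.sort(perm[n_train + n_valid :]),
    }
    return RegressionDataset(records, labels, ind, splits, spec)


# ---------------------------------------------------------------------------
# homology hierarchy


@dataclass(frozen=True)
class HierarchySpec:
    """Fold -> superfamily -> family hierarchy with controlled divergence.

    The three divergence rates are target expected *pairwise* substitution
    fractions: members of one family differ at about
    ``within_family_divergence`` of sites, remote homologs (same
    superfamily, different family) at about
    ``within_superfamily_divergence``, and sequences from different
    superfamilies or folds at ``cross_fold_divergence`` or more.
    """

    n_folds: int = 3
    superfamilies_per_fold: int = 2
    families_per_superfamily: int = 2
    members_per_family: int = 4
    length: int = 60
    within_family_divergence: float = 0.05
    within_superfamily_divergence: float = 0.20
    cross_fold_divergence: float = 0.60
    seed: int = 0

    def __post_init__(self):
        if not (
            0
            <= self.within_family_divergence
            <= self.within_superfamily_divergence
            <= self.cross_fold_divergence
        ):
            raise ValueError("divergence rates must be ordered and non-negative")
        for name in (
            "n_folds",
            "superfamilies_per_fold",
            "families_per_superfamily",
            "members_per_family",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class HomologyDataset:
    records: list[SequenceRecord]
    lineage: pd.DataFrame  # id, fold, superfamily, family, member
    pairs: pd.DataFrame  # id_a, id_b, category
    spec: HierarchySpec


def pair_category(row_a: pd.Series, row_b: pd.Series) -> str:
    """Label one unordered pair from the two lineage rows."""
    if row_a["superfamily"] == row_b["superfamily"]:
        if row_a["family"] == row_b["family"]:
            return "nonremote_homolog"
        return "remote_homolog"
    return "nonhomolog"


def make_homology_dataset(spec: HierarchySpec) -> HomologyDataset:
    """Mutate a common ancestor down the hierarchy and label all pairs.

    Branch substitution rates are set so that the expected pairwise
    divergences (twice the root-to-tip branch sums, ignoring
    back-substitution) match the spec's three rates.
    """
    rng = np.random.default_rng(spec.seed)
    wf, ws, cf = (
        spec.within_family_divergence,
        spec.within_superfamily_divergence,
        spec.cross_fold_divergence,
    )
    b_member = wf / 2
    b_family = (ws - wf) / 2
    b_superfamily = (cf - ws) / 2
    b_fold = cf / 4  # pushes cross-fold pairs past cross-superfamily ones
    ancestor = _random_sequence(spec.length, rng)
    records, rows = [], []
    for f in range(spec.n_folds):
        fold_root = _mutate(ancestor, b_fold, rng)
        for sf in range(spec.superfamilies_per_fold):
            sf_root = _mutate(fold_root, b_superfamily, rng)
            for fam in range(spec.families_per_superfamily):
                fam_root = _mutate(sf_root, b_family, rng)
                for m in range(spec.members_per_family):
                    seq = _mutate(fam_root, b_member, rng)
                    sid = f"f{f}_sf{sf}_fam{fam}_m{m}"
                    records.append(SequenceRecord(sid, seq))
                    rows.append(
                        {
                            "id": sid,
                            "fold": f,
                            "superfamily": f"f{f}_sf{sf}",
                            "family": f"f{f}_sf{sf}_fam{fam}",
                            "member": m,
                        }
                    )
    lineage = pd.DataFrame(rows)
    by_id = lineage.set_index("id")
    pair_rows = [
        {
            "id_a": a,
            "id_b": b,
            "category": pair_category(by_id.loc[a], by_id.loc[b]),
        }
        for a, b in itertools.combinations(lineage["id"], 2)
    ]
    return HomologyDataset(records, lineage, pd.DataFrame(pair_rows), spec)


# ---------------------------------------------------------------------------
# domain-peptide interaction


@dataclass(frozen=True)
class InteractionSpec:
    """Domain-peptide interaction task with a hidden compatibility rule.

    Each of ``n_classes`` domain classes has a signature motif; the motif
    is planted inside every domain of the class, and a peptide interacts
    with a domain iff it carries that class's motif.  ``positive_rate`` is
    the fidelity of the labels (1.0 = noise-free rule).
    """

    n_domains: int = 6
    n_peptides: int = 12
    n_classes: int = 3
    domain_length_range: tuple[int, int] = (80, 120)
    peptide_length: int = 9
    motif_length: int = 6
    positive_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.positive_rate <= 1):
            raise ValueError("positive_rate must be in (0, 1]")
        if self.motif_length > self.peptide_length:
            raise ValueError("motif must fit inside the peptide")
        if self.n_classes > min(self.n_domains, self.n_peptides):
            raise ValueError("need at least one domain and peptide per class")
        lo, hi = self.domain_length_range
        if lo > hi or lo <= self.motif_length:
            raise ValueError("invalid domain_length_range")


@dataclass
class InteractionDataset:
    domains: list[SequenceRecord]
    peptides: list[SequenceRecord]
    domain_class: dict[str, int]
    peptide_motif_class: dict[str, int]
    interactions: pd.DataFrame  # domain_id, peptide_id, interacting
    triplets: pd.DataFrame  # anchor_id (domain), positive_id, negative_id
    spec: InteractionSpec


def make_interaction_dataset(spec: InteractionSpec) -> InteractionDataset:
    rng = np.random.default_rng(spec.seed)
    # distinct class signature motifs
    motifs: list[str] = []
    while len(motifs) < spec.n_classes:
        m = _random_sequence(spec.motif_length, rng)
        if m not in motifs:
            motifs.append(m)
    domains, domain_class = [], {}
    for i in range(spec.n_domains):
        c = i % spec.n_classes
        length = int(rng.integers(*spec.domain_length_range, endpoint=True))
        arr = np.array(list(_random_sequence(length, rng)))
        _plant(arr, motifs[c], rng, set())
        did = f"dom{i:03d}"
        domains.append(SequenceRecord(did, "".join(arr)))
        domain_class[did] = c
    peptides, peptide_class = [], {}
    for j in range(spec.n_peptides):
        c = j % spec.n_classes
        arr = np.array(list(_random_sequence(spec.peptide_length, rng)))
        _plant(arr, motifs[c], rng, set())
        pid = f"pep{j:03d}"
        peptides.append(SequenceRecord(pid, "".join(arr)))
        peptide_class[pid] = c
    rows = []
    for d in domains:
        for p in peptides:
            rule = domain_class[d.id] == peptide_class[p.id]
            label = rule
            if spec.positive_rate < 1.0 and rng.random() > spec.positive_rate:
                label = not rule
            rows.append(
                {"domain_id": d.id, "peptide_id": p.id, "interacting": bool(label)}
            )
    interactions = pd.DataFrame(rows)
    trip_rows = []
    for d in domains:
        sub = interactions[interactions["domain_id"] == d.id]
        pos = sub[sub["interacting"]]["peptide_id"].tolist()
        neg = sub[~sub["interacting"]]["peptide_id"].tolist()
        if not pos or not neg:
            raise ValueError(
                f"domain {d.id} has no {'positive' if not pos else 'negative'} "
                "peptides; adjust the spec"
            )
        for p, n in itertools.product(pos, neg):
            trip_rows.append({"anchor_id": d.id, "positive_id": p, "negative_id": n})
    return InteractionDataset(
        domains,
        peptides,
        domain_class,
        peptide_class,
        interactions,
        pd.DataFrame(trip_rows),
        spec,
    )
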