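"""Metrics and pairwise evaluation protocols against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bompool.evaluation import (
    EvalPairSet,
    interaction_auroc,
    pair_likelihood,
    per_sequence_auroc,
    per_sequence_auroc_report,
    spearman,
)
from bompool.pooling import PoolingParams, WindowConfig


def brute_force_auroc(pos, neg):
    """Mann-Whitney by exhaustive pair counting; ties count one half."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def brute_force_spearman(a, b):
    """Pearson correlation of average ranks, computed from first principles."""

    def avg_ranks(x):
        x = np.asarray(x, dtype=float)
        ranks = np.empty(x.size)
        for i, v in enumerate(x):
            less = np.sum(x < v)
            equal = np.sum(x == v)
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([10, 20, 30], [1, 2, 3]) == 1.0

    def test_antitone_is_minus_one(self):
        assert spearman([30, 20, 10], [1, 2, 3]) == -1.0

    def test_ties_match_average_rank_oracle(self):
        preds, targets = [1, 2, 2, 4], [1, 2, 3, 4]
        assert np.isclose(spearman(preds, targets), brute_force_spearman(preds, targets))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        b = rng.normal(size=20)
        assert np.isclose(spearman(a, b), brute_force_spearman(a, b))

    def test_constant_input_reported_as_nan(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_validation(self):
        with pytest.raises(ValueError):
            spearman([1.0], [1.0])


def _pair_set(rows):
    return EvalPairSet(pd.DataFrame(rows, columns=["id_a", "id_b", "category"]))


class TestPerSequenceAuroc:
    def _likelihoods(self, mapping):
        return {tuple(k): v for k, v in mapping.items()}

    def test_perfect_separation(self):
        ps = _pair_set(
            [("q", "p1", "remote_homolog"), ("q", "n1", "nonhomolog"), ("q", "n2", "nonhomolog")]
        )
        lik = {("q", "p1"): 0.9, ("q", "n1"): 0.1, ("q", "n2"): 0.2}
        assert per_sequence_auroc("q", ps, lik) == 1.0

    def test_all_ties_give_half(self):
        ps = _pair_set([("q", "p1", "remote_homolog"), ("q", "n1", "nonhomolog")])
        lik = {("q", "p1"): 0.5, ("q", "n1"): 0.5}
        assert per_sequence_auroc("q", ps, lik) == 0.5

    def test_counting_example_five_sixths(self):
        ps = _pair_set(
            [("q", "p1", "remote_homolog"), ("q", "p2", "remote_homolog")]
            + [("q", f"n{i}", "nonhomolog") for i in range(3)]
        )
        lik = {
            ("q", "p1"): 0.9,
            ("q", "p2"): 0.4,
            ("q", "n0"): 0.8,
            ("q", "n1"): 0.3,
            ("q", "n2"): 0.1,
        }
        expected = brute_force_auroc([0.9, 0.4], [0.8, 0.3, 0.1])
        assert expected == 5.0 / 6.0
        assert np.isclose(per_sequence_auroc("q", ps, lik), expected)

    def test_nonremote_pairs_excluded(self):
        ps = _pair_set(
            [
                ("q", "p1", "remote_homolog"),
                ("q", "s1", "nonremote_homolog"),  # would be an easy positive
                ("q", "n1", "nonhomolog"),
            ]
        )
        lik = {("q", "p1"): 0.6, ("q", "s1"): 0.99, ("q", "n1"): 0.1}
        assert per_sequence_auroc("q", ps, lik) == 1.0

    def test_query_without_both_classes_raises_and_report_skips(self):
        ps = _pair_set(
            [("q", "p1", "remote_homolog"), ("r", "n1", "nonhomolog")]
        )
        lik = {("q", "p1"): 0.5, ("r", "n1"): 0.5}
        with pytest.raises(ValueError):
            per_sequence_auroc("q", ps, lik)
        report = per_sequence_auroc_report(ps, lik)
        assert report.empty

    def test_invariant_under_increasing_transform(self, rng):
        pos = [f"p{i}" for i in range(3)]
        neg = [f"n{i}" for i in range(4)]
        ps = _pair_set(
            [("q", p, "remote_homolog") for p in pos]
            + [("q", n, "nonhomolog") for n in neg]
        )
        raw = {("q", x): rng.normal() for x in pos + neg}
        warped = {k: np.exp(3 * v) + 1 for k, v in raw.items()}
        assert np.isclose(
            per_sequence_auroc("q", ps, raw), per_sequence_auroc("q", ps, warped)
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 8))
        n_neg = int(rng.integers(1, 20 - n_pos))
        pos = [f"p{i}" for i in range(n_pos)]
        neg = [f"n{i}" for i in range(n_neg)]
        ps = _pair_set(
            [("q", p, "remote_homolog") for p in pos]
            + [("q", n, "nonhomolog") for n in neg]
        )
        lik = {("q", x): float(rng.integers(0, 4)) for x in pos + neg}  # ties likely
        expected = brute_force_auroc(
            [lik[("q", p)] for p in pos], [lik[("q", n)] for n in neg]
        )
        assert np.isclose(per_sequence_auroc("q", ps, lik), expected)


class TestInteractionAuroc:
    def test_dataframe_form_and_single_class_rejected(self):
        df = pd.DataFrame(
            {"interacting": [True, False, True], "likelihood": [0.9, 0.1, 0.8]}
        )
        assert interaction_auroc(df) == 1.0
        with pytest.raises(ValueError):
            interaction_auroc(df[df["interacting"]])

    def test_pairset_form_matches_brute_force(self, rng):
        rows, lik = [], {}
        for i in range(10):
            cat = "interacting" if i % 3 == 0 else "noninteracting"
            rows.append((f"d{i%2}", f"p{i}", cat))
            lik[(f"d{i%2}", f"p{i}")] = float(rng.integers(0, 3))
        ps = _pair_set(rows)
        pos = [lik[(a, b)] for a, b, c in rows if c == "interacting"]
        neg = [lik[(a, b)] for a, b, c in rows if c == "noninteracting"]
        assert np.isclose(interaction_auroc(ps, lik), brute_force_auroc(pos, neg))


class TestPairLikelihood:
    def test_identical_inputs_score_zero(self, embed_seq):
        H = embed_seq("ACDEFGHIKL")
        assert np.isclose(pair_likelihood(H, H, "avg"), 0.0, atol=1e-9)

    def test_orthogonal_pooled_vectors_score_minus_one(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        assert np.isclose(pair_likelihood(a, b, "avg"), -1.0)

    def test_cross_bom_score_symmetric_under_swap(self, embed_seq):
        params = PoolingParams.init(16, seed=4)
        w = WindowConfig(4, 2)
        Ha, Hb = embed_seq("ACDEFGHIKLMNP"), embed_seq("WYWHCKDEACDFG")
        s_ab = pair_likelihood(Ha, Hb, "bom_cross", params, w)
        s_ba = pair_likelihood(Hb, Ha, "bom_cross", params, w)
        assert np.isclose(s_ab, s_ba)

    def test_unknown_method_rejected(self, embed_seq):
        with pytest.raises(ValueError):
            pair_likelihood(embed_seq("ACD"), embed_seq("ACD"), "median")


class TestEvalPairSet:
    def test_duplicate_unordered_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _pair_set([("a", "b", "nonhomolog"), ("b", "a", "remote_homolog")])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            _pair_set([("a", "b", "friends")])
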