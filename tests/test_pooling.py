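"""Pooling operators: definitions, reduction identities, window dialect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bompool.pooling import (
    MLPTransform,
    PoolingParams,
    WindowConfig,
    attention_weights,
    bom_cross_pool,
    bom_self_pool,
    count_windows,
    count_windows_printed_formula,
    cross_attention_pool,
    local_avg_pool,
    pool_avg,
    pool_cls,
    pool_eos,
    self_attention_pool,
    trainable_global_pool,
)
from bompool.providers import TokenEmbeddingMatrix


def brute_force_bag(rows: np.ndarray, k: int, s: int, tail: bool = True):
    """Independent window-mean oracle via explicit index lists."""
    l = rows.shape[0]  # noqa: E741
    if l < k:
        return [list(range(l))]
    windows = []
    start = 0
    while start + k <= l:
        windows.append(list(range(start, start + k)))
        start += s
    if tail and windows[-1][-1] < l - 1:
        tail_start = min(start, windows[-1][-1] + 1)
        windows.append(list(range(tail_start, l)))
    return windows


# ---------------------------------------------------------------------------
# global pooling


class TestGlobalPooling:
    def test_cls_is_first_row_eos_is_last(self):
        H = TokenEmbeddingMatrix(np.arange(12.0).reshape(3, 4), True, True, "x")
        assert np.array_equal(pool_cls(H).values, H.values[0])
        assert np.array_equal(pool_eos(H).values, H.values[-1])

    def test_cls_requires_flag(self):
        H = TokenEmbeddingMatrix(np.ones((3, 2)))
        with pytest.raises(ValueError):
            pool_cls(H)
        with pytest.raises(ValueError):
            pool_eos(H)

    def test_avg_arithmetic_and_special_masking(self):
        plain = TokenEmbeddingMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.array_equal(pool_avg(plain).values, [2.0, 3.0])
        flagged = TokenEmbeddingMatrix(
            np.array([[9.0, 9.0], [1.0, 2.0], [3.0, 4.0], [9.0, 9.0]]), True, True
        )
        assert np.array_equal(pool_avg(flagged).values, [2.0, 3.0])
        assert np.array_equal(
            pool_avg(flagged, include_special=True).values, [5.5, 6.0]
        )

    def test_avg_linearity_over_halves(self, random_matrix):
        rows = random_matrix(10, 4)
        halves = 0.5 * (
            pool_avg(rows[:5]).values + pool_avg(rows[5:]).values
        )
        assert np.allclose(halves, pool_avg(rows).values)

    def test_avg_rejects_empty_selection(self):
        only_special = TokenEmbeddingMatrix(np.ones((2, 3)), True, True)
        with pytest.raises(ValueError):
            pool_avg(only_special)

    def test_avg_permutation_invariant(self, random_matrix, rng):
        rows = random_matrix(8, 3)
        assert np.allclose(
            pool_avg(rows).values, pool_avg(rows[rng.permutation(8)]).values
        )


class TestTrainableGlobalPooling:
    def test_zero_maps_annihilate(self, random_matrix):
        params = PoolingParams(
            MLPTransform.zeros(4, 3), MLPTransform.zeros(4, 3), MLPTransform.zeros(4, 3)
        )
        out = trainable_global_pool(random_matrix(5, 4), "avg", params)
        assert np.array_equal(out.values, np.zeros(3))

    def test_identity_q_recovers_vanilla(self, random_matrix):
        params = PoolingParams(
            MLPTransform.identity(4), MLPTransform.zeros(4, 4), MLPTransform.zeros(4, 4)
        )
        rows = random_matrix(5, 4)
        assert np.allclose(
            trainable_global_pool(rows, "avg", params).values, pool_avg(rows).values
        )

    def test_same_parameter_count_as_attention_variants(self, make_params):
        # both constructions share one PoolingParams architecture, so the
        # trainable-global and attention operators are parameter-matched
        params = make_params(16, 8, hidden=(12,))
        per_map = 16 * 12 + 12 + 12 * 8 + 8
        assert params.n_params == 3 * per_map

    def test_unknown_base_rejected(self, make_params, random_matrix):
        with pytest.raises(ValueError):
            trainable_global_pool(random_matrix(3, 4), "max", make_params(4))


# ---------------------------------------------------------------------------
# attention pooling


class TestAttentionPooling:
    def test_constant_maps_give_uniform_weights(self, random_matrix):
        params = PoolingParams(
            MLPTransform.constant(4, np.ones(4)),
            MLPTransform.constant(4, np.full(4, 2.0)),
            MLPTransform.identity(4),
        )
        w = attention_weights(random_matrix(5, 4), random_matrix(7, 4), params).value
        assert w.shape == (5, 7)
        assert np.allclose(w, 1.0 / 7.0)

    def test_single_entry_softmax(self, make_params, random_matrix):
        w = attention_weights(
            random_matrix(1, 4), random_matrix(1, 4), make_params(4)
        ).value
        assert np.allclose(w, [[1.0]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lq=st.integers(1, 8),
        lk=st.integers(1, 8),
        seed=st.integers(0, 100),
    )
    def test_rows_sum_to_one_nonnegative(self, lq, lk, seed):
        rng = np.random.default_rng(seed)
        params = PoolingParams.init(3, 4, seed=seed)
        w = attention_weights(rng.normal(size=(lq, 3)), rng.normal(size=(lk, 3)), params)
        assert np.all(w.value >= 0)
        assert np.allclose(w.value.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self, make_params, random_matrix):
        with pytest.raises(ValueError):
            attention_weights(random_matrix(3, 4), random_matrix(3, 5), make_params(4))

    def test_uniform_attention_identity_v_reduces_to_avg(self, random_matrix):
        params = PoolingParams(
            MLPTransform.constant(4, np.zeros(4)),
            MLPTransform.constant(4, np.zeros(4)),
            MLPTransform.identity(4),
        )
        rows = random_matrix(9, 4)
        assert np.allclose(
            self_attention_pool(rows, params).values, pool_avg(rows).values, atol=1e-12
        )

    def test_single_row_gives_v_of_row(self, make_params, random_matrix):
        params = make_params(4, 6)
        rows = random_matrix(1, 4)
        assert np.allclose(
            self_attention_pool(rows, params).values, params.V(rows[0]).value
        )

    def test_cross_on_same_input_equals_self(self, make_params, random_matrix):
        params = make_params(4, 5)
        rows = random_matrix(6, 4)
        assert np.array_equal(
            cross_attention_pool(rows, rows, params).values,
            self_attention_pool(rows, params).values,
        )

    def test_cross_is_asymmetric(self, make_params, random_matrix):
        params = make_params(4, 5)
        a, b = random_matrix(6, 4), random_matrix(9, 4)
        ab = cross_attention_pool(a, b, params).values
        ba = cross_attention_pool(b, a, params).values
        assert not np.allclose(ab, ba)

    def test_uniform_cross_attention_ignores_query(self, random_matrix):
        params = PoolingParams(
            MLPTransform.constant(4, np.zeros(4)),
            MLPTransform.constant(4, np.zeros(4)),
            MLPTransform.identity(4),
        )
        b = random_matrix(5, 4)
        out1 = cross_attention_pool(random_matrix(3, 4), b, params).values
        out2 = cross_attention_pool(random_matrix(7, 4), b, params).values
        assert np.allclose(out1, out2)
        assert np.allclose(out1, pool_avg(b).values, atol=1e-12)

    def test_permutation_behaviour_of_attention_vs_bom(self, make_params, rng):
        """Uniform-row-average attention pooling is invariant to reordering
        the tokens (permuting H permutes queries, keys and values
        consistently); windowed BoM pooling with k >= 2 is not, because the
        window contents change — locality is what breaks the symmetry."""
        params = make_params(4, 4)
        rows = rng.normal(size=(8, 4))
        perm = np.roll(np.arange(8), 3)
        out = self_attention_pool(rows, params).values
        out_p = self_attention_pool(rows[perm], params).values
        assert np.allclose(out, out_p)
        bom = bom_self_pool(rows, WindowConfig(3, 2), params).values
        bom_p = bom_self_pool(rows[perm], WindowConfig(3, 2), params).values
        assert not np.allclose(bom, bom_p)


# ---------------------------------------------------------------------------
# windows


class TestWindows:
    def test_complete_window_count_without_tail(self):
        assert count_windows(10, WindowConfig(3, 2, tail=False)) == 4

    def test_tail_window_appended_when_uncovered(self):
        assert count_windows(10, WindowConfig(3, 2, tail=True)) == 5
        # exact cover leaves no tail
        assert count_windows(10, WindowConfig(2, 2, tail=True)) == 5

    def test_printed_formula_differs_and_overruns(self):
        cfg = WindowConfig(3, 2, tail=False)
        printed = count_windows_printed_formula(10, cfg)
        assert printed == 5
        # the printed count's last window would start at s*(n-1)+1 = 9 and
        # cover 9..11, past l=10 — hence the emitted-bag dialect
        assert cfg.s * (printed - 1) + cfg.k > 10
        assert count_windows(10, cfg) == 4

    def test_short_sequence_single_window(self):
        assert count_windows(5, WindowConfig(7, 3)) == 1

    def test_local_avg_arithmetic(self):
        rows = np.array([[1.0], [3.0], [5.0], [7.0]])
        bag = local_avg_pool(rows, WindowConfig(2, 2))
        assert np.array_equal(bag.omegas, [[2.0], [6.0]])
        assert np.array_equal(bag.starts, [1, 3])

    def test_unit_windows_reproduce_rows_bitwise(self, random_matrix):
        rows = random_matrix(11, 5)
        bag = local_avg_pool(rows, WindowConfig(1, 1))
        assert np.array_equal(bag.omegas, rows)

    def test_windows_match_brute_force_oracle(self, random_matrix):
        rows = random_matrix(23, 4)
        bag = local_avg_pool(rows, WindowConfig(5, 3))
        expected = brute_force_bag(rows, 5, 3)
        assert bag.n == len(expected)
        for i, idx in enumerate(expected):
            assert np.allclose(bag.omegas[i], rows[idx].mean(axis=0))
            assert bag.starts[i] == idx[0] + 1
            assert bag.lengths[i] == len(idx)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        l=st.integers(1, 50),
        k=st.integers(1, 10),
        s=st.integers(1, 5),
        tail=st.booleans(),
    )
    def test_window_dialect_property(self, l, k, s, tail):  # noqa: E741
        rng = np.random.default_rng(l * 1000 + k * 50 + s)
        rows = rng.normal(size=(l, 3))
        bag = local_avg_pool(rows, WindowConfig(k, s, tail))
        expected = brute_force_bag(rows, k, s, tail)
        assert bag.n == len(expected) == count_windows(l, WindowConfig(k, s, tail))
        for i, idx in enumerate(expected):
            assert np.allclose(bag.omegas[i], rows[idx].mean(axis=0))

    def test_exact_cover_bag_mean_equals_global_mean(self, random_matrix):
        rows = random_matrix(20, 3)
        bag = local_avg_pool(rows, WindowConfig(5, 5))
        assert np.allclose(bag.omegas.mean(axis=0), pool_avg(rows).values)


# ---------------------------------------------------------------------------
# BoM pooling


class TestBomPooling:
    def test_unit_window_bom_is_full_attention_bitwise(self, embed_seq, make_params):
        H = embed_seq("ACDEFGHIKLMNPQRSTVWY")
        params = make_params(16, 8)
        bom = bom_self_pool(H, WindowConfig(1, 1), params)
        full = self_attention_pool(H, params)
        assert np.array_equal(bom.values, full.values)

    def test_unit_window_cross_bom_is_cross_attention_bitwise(
        self, embed_seq, make_params
    ):
        Ha, Hb = embed_seq("ACDEFGHIKL"), embed_seq("WYWHCKDEAC")
        params = make_params(16, 8)
        assert np.array_equal(
            bom_cross_pool(Ha, Hb, WindowConfig(1, 1), params).values,
            cross_attention_pool(Ha, Hb, params).values,
        )

    def test_whole_sequence_window_collapses_to_v_of_mean(
        self, make_params, random_matrix
    ):
        rows = random_matrix(12, 4)
        params = make_params(4, 6)
        out = bom_self_pool(rows, WindowConfig(12, 12), params)
        assert np.allclose(out.values, params.V(pool_avg(rows).values).value)

    def test_cross_bom_on_same_input_equals_self(self, make_params, random_matrix):
        rows = random_matrix(15, 4)
        params = make_params(4)
        assert np.array_equal(
            bom_cross_pool(rows, rows, WindowConfig(4, 2), params).values,
            bom_self_pool(rows, WindowConfig(4, 2), params).values,
        )

    def test_short_peptide_contributes_single_window(self, make_params, random_matrix):
        pep = random_matrix(9, 4)
        dom = random_matrix(100, 4)
        cfg = WindowConfig(60, 20)
        assert local_avg_pool(pep, cfg).n == 1
        out = bom_cross_pool(dom, pep, cfg, make_params(4))
        assert out.values.shape == (4,)

    def test_bag_attention_cost_scales_down(self):
        cfg = WindowConfig(100, 80)
        n = count_windows(1000, cfg)
        assert n**2 * 50 <= 1000**2
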