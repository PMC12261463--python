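"""Regression head and contrastive objectives."""

import numpy as np
import pytest

from bompool.heads import (
    ContrastiveConfig,
    RegressionHead,
    RegressionHeadConfig,
    Triplet,
    cosine_distance,
    cross_bom_triplet_loss,
    mse_loss,
    triplet_loss,
)
from bompool.pooling import PoolingParams, WindowConfig, cross_attention_pool


class TestRegressionHead:
    def test_parameter_count_closed_form(self):
        head = RegressionHead(RegressionHeadConfig(640))
        affine = 640 * 256 + 256 + 256 * 64 + 64 + 64 * 1 + 1
        norm = 2 * 256 + 2 * 64  # gamma and beta per normalized layer
        assert head.n_params == affine + norm

    def test_eval_forward_is_deterministic(self, rng):
        head = RegressionHead(RegressionHeadConfig(8, hidden_dims=(6, 4)))
        x = rng.normal(size=(5, 8))
        a = head.forward(x, training=False).value
        b = head.forward(x, training=False).value
        assert np.array_equal(a, b)

    def test_zero_weights_predict_zero(self, rng):
        head = RegressionHead(RegressionHeadConfig(8, hidden_dims=(6, 4)))
        for p in head.weights + head.biases + head.betas:
            p.value = np.zeros_like(p.value)
        out = head.forward(rng.normal(size=(3, 8)), training=False).value
        assert np.allclose(out, 0.0)

    def test_train_mode_dropout_seeded(self, rng):
        head = RegressionHead(RegressionHeadConfig(8, hidden_dims=(6, 4)))
        x = rng.normal(size=(4, 8))
        a = head.forward(x, training=True, rng=np.random.default_rng(3)).value
        b = head.forward(x, training=True, rng=np.random.default_rng(3)).value
        # same dropout seed but batch-norm running stats were updated between
        # calls only; per-batch statistics are identical, so outputs agree
        assert np.allclose(a, b)

    def test_batch_norm_needs_batch_of_two(self, rng):
        head = RegressionHead(RegressionHeadConfig(8))
        with pytest.raises(ValueError, match="batch size"):
            head.forward(rng.normal(size=(1, 8)), training=True)

    def test_dimension_mismatch_rejected(self, rng):
        head = RegressionHead(RegressionHeadConfig(8))
        with pytest.raises(ValueError):
            head.forward(rng.normal(size=(3, 9)))

    def test_state_roundtrip(self, rng):
        cfg = RegressionHeadConfig(6, hidden_dims=(5, 3))
        a = RegressionHead(cfg, seed=1)
        b = RegressionHead(cfg, seed=2)
        b.load_state_dict(a.state_dict())
        x = rng.normal(size=(4, 6))
        assert np.array_equal(
            a.forward(x, training=False).value, b.forward(x, training=False).value
        )


class TestMSE:
    def test_zero_on_equal(self):
        assert float(mse_loss([1.0, 2.0], [1.0, 2.0]).value) == 0.0

    def test_arithmetic(self):
        assert float(mse_loss([0.0, 0.0], [1.0, 3.0]).value) == 5.0

    def test_permutation_symmetric(self, rng):
        p = rng.normal(size=10)
        t = rng.normal(size=10)
        perm = rng.permutation(10)
        assert np.isclose(
            float(mse_loss(p, t).value), float(mse_loss(p[perm], t[perm]).value)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([], [])


class TestTripletLoss:
    def _vectors_at_distances(self, d_pos, d_neg):
        """Anchor e1; partners in the e1-e2 plane at given cosine distances."""

        def at(dist):
            cos = 1.0 - dist
            return np.array([cos, np.sqrt(1 - cos**2), 0.0])

        return np.array([1.0, 0.0, 0.0]), at(d_pos), at(d_neg)

    @pytest.mark.parametrize(
        "d_pos,d_neg,expected",
        [(0.1, 0.9, 0.0), (0.5, 0.2, 0.9)],
    )
    def test_printed_formula_values(self, d_pos, d_neg, expected):
        a, p, n = self._vectors_at_distances(d_pos, d_neg)
        loss = triplet_loss(a, p, n, ContrastiveConfig(margin=0.6))
        assert np.isclose(float(loss.value), expected, atol=1e-12)

    def test_equal_partners_give_margin(self, rng):
        a = rng.normal(size=5)
        p = rng.normal(size=5)
        loss = triplet_loss(a, p, p, ContrastiveConfig(margin=0.6))
        assert np.isclose(float(loss.value), 0.6)

    def test_loss_bounded(self, rng):
        cfg = ContrastiveConfig(margin=0.6)
        for _ in range(50):
            vals = [rng.normal(size=4) for _ in range(3)]
            v = float(triplet_loss(*vals, cfg).value)
            assert 0.0 <= v <= 2.0 + cfg.margin

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            cosine_distance(np.zeros(3), np.ones(3))

    def test_margin_validation(self):
        with pytest.raises(ValueError):
            ContrastiveConfig(margin=-0.1)


class TestCrossBomTripletLoss:
    def test_equal_partners_give_margin(self, rng):
        params = PoolingParams.init(4, seed=0)
        Ha, Hp = rng.normal(size=(20, 4)), rng.normal(size=(15, 4))
        loss = cross_bom_triplet_loss(
            Ha, Hp, Hp, WindowConfig(4, 2), params, ContrastiveConfig(0.6)
        )
        assert np.isclose(float(loss.value), 0.6)

    def test_unit_windows_match_direct_cross_attention(self, rng):
        params = PoolingParams.init(4, seed=1)
        Ha, Hp, Hn = (rng.normal(size=(l, 4)) for l in (8, 6, 7))
        loss = cross_bom_triplet_loss(
            Ha, Hp, Hn, WindowConfig(1, 1), params, ContrastiveConfig(0.6)
        )
        d_pos = cosine_distance(
            cross_attention_pool(Ha, Hp, params).values,
            cross_attention_pool(Hp, Ha, params).values,
        )
        d_neg = cosine_distance(
            cross_attention_pool(Ha, Hn, params).values,
            cross_attention_pool(Hn, Ha, params).values,
        )
        direct = max(0.0, float(d_pos.value) - float(d_neg.value) + 0.6)
        assert np.isclose(float(loss.value), direct)

    def test_differs_from_self_pooled_objective(self, rng):
        from bompool.pooling import bom_self_pool

        # non-uniform attention (qk_init_scale=1) so the pair-dependent
        # representations genuinely differ from the self-pooled ones
        params = PoolingParams.init(4, seed=2, qk_init_scale=1.0)
        w = WindowConfig(3, 2)
        Ha, Hp, Hn = (rng.normal(size=(l, 4)) for l in (12, 10, 11))
        cross = float(cross_bom_triplet_loss(Ha, Hp, Hn, w, params).value)
        self_pooled = float(
            triplet_loss(
                bom_self_pool(Ha, w, params).values,
                bom_self_pool(Hp, w, params).values,
                bom_self_pool(Hn, w, params).values,
            ).value
        )
        assert not np.isclose(cross, self_pooled)

    def test_gradient_matches_finite_differences(self, rng):
        params = PoolingParams.init(3, 2, hidden=(3,), seed=3)
        Ha, Hp, Hn = (rng.normal(size=(l, 3)) for l in (6, 5, 4))
        w = WindowConfig(2, 2)

        def loss():
            return cross_bom_triplet_loss(Ha, Hp, Hn, w, params)

        out = loss()
        out.backward()
        eps = 1e-6
        for p in params.parameters():
            flat = p.value.ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                old = flat[idx]
                flat[idx] = old + eps
                fp = float(loss().value)
                flat[idx] = old - eps
                fm = float(loss().value)
                flat[idx] = old
                fd = (fp - fm) / (2 * eps)
                assert abs(fd - p.grad.ravel()[idx]) < 1e-4


def test_triplet_requires_distinct_ids():
    with pytest.raises(ValueError):
        Triplet("a", "a", "b")
    Triplet("a", "b", "c")
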