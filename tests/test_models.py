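"""Prediction heads: pooling, (gated) attention MIL, multi-omics fusion."""

import numpy as np
import pytest
from scipy.special import expit

from pikn.models import (AttentionKernelNet, AttentionParams, MultiOmicsKernelNet,
                         PoolingHeadParams, PoolingKernelNet, attention_forward,
                         attention_pool, attention_weights, load_checkpoint,
                         max_pool_activation, multiomics_forward, pooling_forward,
                         save_checkpoint)
from pikn.pathways import pathway_laplacian
from pikn.simulate import SimulationConfig, simulate_expression, simulate_pathways
from pikn.training import TrainConfig, train
from pikn.training import _loss_grad  # noqa: F401  (used by gradient smoke test)


def small_attention(l=2, m=2, gated=True, seed=0):
    rng = np.random.default_rng(seed)
    return AttentionParams(w=rng.standard_normal(l), V=rng.standard_normal((l, m)),
                           U=rng.standard_normal((l, m)) if gated else None, gated=gated)


class TestMaxPool:
    def test_examples(self):
        assert max_pool_activation([0.2, -1.0, 0.7]) == 0.7
        assert max_pool_activation([3.0, 3.0]) == 3.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            max_pool_activation([])

    def test_monotone_in_entries(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            psi = rng.standard_normal(6)
            bumped = psi.copy()
            i = rng.integers(6)
            bumped[i] += abs(rng.standard_normal())
            assert max_pool_activation(bumped) >= max_pool_activation(psi)


class TestPoolingHead:
    def test_weighted_sum(self):
        head = PoolingHeadParams(weights=[0.5, -0.25])
        rec = pooling_forward([np.array([2.0, 1.0]), np.array([4.0, 0.0])], head)
        assert rec.score == pytest.approx(0.0)
        assert rec.probability == pytest.approx(0.5)

    def test_zero_weights(self):
        rng = np.random.default_rng(1)
        head = PoolingHeadParams(weights=np.zeros(3))
        rec = pooling_forward(list(rng.standard_normal((3, 4))), head)
        assert rec.score == 0.0

    def test_matches_handrolled_oracle(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal(5)
        embeddings = list(rng.standard_normal((5, 7)))
        rec = pooling_forward(embeddings, PoolingHeadParams(weights=w))
        oracle = sum(w[r] * max(embeddings[r]) for r in range(5))
        assert rec.score == pytest.approx(oracle, abs=1e-10)
        assert np.allclose(rec.per_pathway, [e.max() for e in embeddings])

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal(4)
        em = list(rng.standard_normal((4, 3)))
        s1 = pooling_forward(em, PoolingHeadParams(weights=w)).score
        s2 = pooling_forward(em, PoolingHeadParams(weights=2 * w)).score
        assert s2 == pytest.approx(2 * s1, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pooling_forward([np.ones(2)], PoolingHeadParams(weights=[1.0, 2.0]))

    def test_sign_determines_direction(self):
        # raising A_r increases the score iff w_r > 0
        w = np.array([0.8, -0.6])
        em = [np.array([1.0, 0.0]), np.array([2.0, 0.5])]
        base = pooling_forward(em, PoolingHeadParams(weights=w)).score
        up0 = pooling_forward([em[0] + 1.0, em[1]], PoolingHeadParams(weights=w)).score
        up1 = pooling_forward([em[0], em[1] + 1.0], PoolingHeadParams(weights=w)).score
        assert up0 > base and up1 < base


class TestAttention:
    @pytest.mark.parametrize("gated", [True, False])
    def test_identical_instances_give_uniform_weights(self, gated):
        params = small_attention(gated=gated, m=3)
        bag = np.tile(np.array([0.3, -0.2, 1.1]), (4, 1))
        assert np.allclose(attention_weights(bag, params), np.full(4, 0.25), atol=1e-12)

    def test_zero_w_gives_uniform(self):
        params = small_attention(m=2)
        params.w = np.zeros_like(params.w)
        rng = np.random.default_rng(4)
        a = attention_weights(rng.standard_normal((5, 2)), params)
        assert np.allclose(a, 0.2, atol=1e-12)

    @pytest.mark.parametrize("gated", [True, False])
    def test_matches_scalar_oracle(self, gated):
        """Step-by-step scalar recomputation of the softmax attention."""
        params = small_attention(l=2, m=2, gated=gated, seed=5)
        rng = np.random.default_rng(6)
        H = rng.standard_normal((3, 2))
        logits = []
        for r in range(3):
            t = np.tanh(params.V @ H[r])
            if gated:
                t = t * expit(params.U @ H[r])
            logits.append(float(params.w @ t))
        e = np.exp(np.array(logits))
        oracle = e / e.sum()
        assert np.allclose(attention_weights(H, params), oracle, atol=1e-8)

    def test_weights_nonnegative_and_normalized(self):
        rng = np.random.default_rng(7)
        params = small_attention(l=3, m=4, seed=8)
        for _ in range(25):
            a = attention_weights(rng.standard_normal((6, 4)) * 5, params)
            assert np.all(a >= 0)
            assert a.sum() == pytest.approx(1.0, abs=1e-6)

    def test_pool_single_instance(self):
        bag = np.array([[1.0, 2.0, 3.0]])
        assert np.array_equal(attention_pool(bag, [1.0]), bag[0])

    def test_pool_uniform_is_mean(self):
        rng = np.random.default_rng(9)
        bag = rng.standard_normal((4, 3))
        assert np.allclose(attention_pool(bag, np.full(4, 0.25)), bag.mean(axis=0), atol=1e-12)

    def test_pool_matches_loop(self):
        rng = np.random.default_rng(10)
        bag = rng.standard_normal((5, 4))
        a = rng.random(5)
        a /= a.sum()
        oracle = sum(a[r] * bag[r] for r in range(5))
        assert np.allclose(attention_pool(bag, a), oracle, atol=1e-10)

    def test_pool_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            attention_pool(np.ones((2, 2)), [0.7, 0.7])

    def test_forward_identical_instances(self):
        params = small_attention(m=3, seed=11)
        inst = np.array([0.4, -1.0, 0.3])
        c = np.array([1.0, 2.0, -0.5])
        rec = attention_forward([inst, inst, inst], params, c)
        assert rec.score == pytest.approx(float(c @ inst), abs=1e-10)

    def test_forward_zero_classifier(self):
        params = small_attention(m=2, seed=12)
        rng = np.random.default_rng(13)
        rec = attention_forward(list(rng.standard_normal((4, 2))), params, np.zeros(2))
        assert rec.score == 0.0

    def test_forward_matches_composed_oracle(self):
        params = small_attention(l=3, m=4, seed=14)
        rng = np.random.default_rng(15)
        em = list(rng.standard_normal((5, 4)))
        c = rng.standard_normal(4)
        rec = attention_forward(em, params, c)
        H = np.vstack(em)
        a = attention_weights(H, params)
        assert rec.score == pytest.approx(float(c @ attention_pool(H, a)), abs=1e-10)
        assert np.allclose(rec.per_pathway, a)

    def test_permutation_equivariance(self):
        params = small_attention(l=2, m=3, seed=16)
        rng = np.random.default_rng(17)
        em = list(rng.standard_normal((6, 3)))
        c = rng.standard_normal(3)
        rec = attention_forward(em, params, c, pathway_ids=[f"p{i}" for i in range(6)])
        perm = rng.permutation(6)
        rec_p = attention_forward([em[i] for i in perm], params, c,
                                  pathway_ids=[f"p{i}" for i in perm])
        assert rec_p.score == pytest.approx(rec.score, abs=1e-10)
        assert np.allclose(rec_p.per_pathway, rec.per_pathway[perm], atol=1e-12)

    def test_gated_requires_U(self):
        with pytest.raises(ValueError, match="U"):
            AttentionParams(w=np.ones(2), V=np.ones((2, 2)), U=None, gated=True)


class TestMultiomicsForward:
    def test_single_modality_attention_is_one(self):
        rng = np.random.default_rng(18)
        fusion = small_attention(l=2, m=3, seed=19)
        rec = multiomics_forward(
            {"expr": list(rng.standard_normal((4, 5)))},
            {"expr": rng.standard_normal((3, 4))},
            fusion, rng.standard_normal(3))
        assert rec.per_pathway[0] == pytest.approx(1.0)

    def test_two_identical_modalities_split_evenly(self):
        rng = np.random.default_rng(20)
        em = list(rng.standard_normal((4, 5)))
        P = rng.standard_normal((3, 4))
        fusion = small_attention(l=2, m=3, seed=21)
        rec = multiomics_forward({"a": em, "b": [e.copy() for e in em]},
                                 {"a": P, "b": P.copy()}, fusion, rng.standard_normal(3))
        assert np.allclose(rec.per_pathway, [0.5, 0.5], atol=1e-12)

    def test_matches_composed_oracle(self):
        rng = np.random.default_rng(22)
        em_a = list(rng.standard_normal((3, 4)))
        em_b = list(rng.standard_normal((5, 4)))
        Pa, Pb = rng.standard_normal((6, 3)), rng.standard_normal((6, 5))
        fusion = small_attention(l=2, m=6, seed=23)
        c = rng.standard_normal(6)
        rec = multiomics_forward({"a": em_a, "b": em_b}, {"a": Pa, "b": Pb}, fusion, c)
        va = Pa @ np.array([e.max() for e in em_a])
        vb = Pb @ np.array([e.max() for e in em_b])
        H = np.vstack([va, vb])
        a = attention_weights(H, fusion)
        assert rec.score == pytest.approx(float(c @ attention_pool(H, a)), abs=1e-10)

    def test_zero_modalities_errors(self):
        with pytest.raises(ValueError):
            multiomics_forward({}, {}, small_attention(), np.ones(2))


@pytest.fixture(scope="module")
def tiny_setup():
    pathways = simulate_pathways(3, (4, 6), seed=30)
    cfg = SimulationConfig(n_samples=40, n_pathways=3, informative_set=(0,), seed=31)
    data = simulate_expression(cfg, pathways)
    laps = [pathway_laplacian(pw) for pw in pathways]
    return laps, data.modalities["expression"]


class TestGradientFlow:
    @pytest.mark.parametrize("kind", ["pooling", "attention"])
    def test_every_parameter_receives_gradient(self, tiny_setup, kind):
        laps, ds = tiny_setup
        if kind == "pooling":
            model = PoolingKernelNet(laps, q=4, init_seed=1)
        else:
            model = AttentionKernelNet(laps, q=4, attention_dim=5, init_seed=1)
        model.init_anchors(ds, 2)
        scores, cache = model.forward_scores(ds, training=True)
        grads = model.backward(cache, _loss_grad(scores, ds.labels, np.ones(2)))
        for name, g in grads.items():
            assert np.abs(g).max() > 0, f"zero gradient for {name}"

    def test_multiomics_gradient_flow(self, tiny_setup):
        laps, ds = tiny_setup
        model = MultiOmicsKernelNet({"expression": laps, "cna": laps}, q=4,
                                    fusion_dim=5, init_seed=1)
        data = {"expression": ds, "cna": ds}
        model.init_anchors(data, 2)
        scores, cache = model.forward_scores(data, training=True)
        grads = model.backward(cache, _loss_grad(scores, ds.labels, np.ones(2)))
        for name, g in grads.items():
            assert np.abs(g).max() > 0, f"zero gradient for {name}"


class TestCheckpoint:
    @pytest.mark.parametrize("kind", ["pooling", "attention"])
    def test_round_trip_preserves_predictions(self, tiny_setup, tmp_path, kind):
        laps, ds = tiny_setup
        if kind == "pooling":
            model = PoolingKernelNet(laps, q=4, init_seed=3)
        else:
            model = AttentionKernelNet(laps, q=4, attention_dim=5, init_seed=3)
        model, _ = train(model, ds, TrainConfig(epochs=2, seed=3, anchor_init_seed=3))
        path = tmp_path / "model.zip"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert np.allclose(back.predict_scores(ds), model.predict_scores(ds), atol=1e-12)

    def test_multiomics_round_trip(self, tiny_setup, tmp_path):
        laps, ds = tiny_setup
        model = MultiOmicsKernelNet({"expression": laps, "cna": laps}, q=4, init_seed=3)
        data = {"expression": ds, "cna": ds}
        model, _ = train(model, data, TrainConfig(epochs=2, seed=3, anchor_init_seed=3))
        path = tmp_path / "multi.zip"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert np.allclose(back.predict_scores(data), model.predict_scores(data), atol=1e-12)
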