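"""CP reconstruction, factorized contraction, forward/predict, manual
gradients and training behaviour of the Rank-R FNN."""

import numpy as np
import pytest

from mammotensor.rankr_fnn import (
    CPNeuronFactors,
    ModelDims,
    TrainConfig,
    count_parameters,
    cp_reconstruct,
    cross_entropy,
    fit_arrays,
    forward,
    hidden_preactivation,
    init_params,
    loss_and_grads,
    predict,
)


def brute_force_reconstruct(factors):
    """Triple-loop outer-product sum, independent of any einsum."""
    R, s = factors.w1.shape
    b = factors.w3.shape[1]
    W = np.zeros((s, s, b))
    for k in range(R):
        for j in range(s):
            for l in range(s):
                for m in range(b):
                    W[j, l, m] += factors.w1[k, j] * factors.w2[k, l] * factors.w3[k, m]
    return W


class TestCPReconstruct:
    def test_rank1_by_hand(self):
        f = CPNeuronFactors(w1=[[1.0, 0.0]], w2=[[1.0, 1.0]], w3=[[2.0]])
        W = cp_reconstruct(f)
        np.testing.assert_array_equal(W[:, :, 0], [[2.0, 2.0], [0.0, 0.0]])

    def test_zero_channel_factor_annihilates(self):
        rng = np.random.default_rng(0)
        f = CPNeuronFactors(w1=rng.normal(size=(3, 4)), w2=rng.normal(size=(3, 4)),
                            w3=np.zeros((3, 2)))
        assert (cp_reconstruct(f) == 0).all()

    def test_rank2_equals_sum_of_rank1s(self):
        rng = np.random.default_rng(1)
        w1, w2, w3 = rng.normal(size=(2, 5)), rng.normal(size=(2, 5)), rng.normal(size=(2, 3))
        full = cp_reconstruct(CPNeuronFactors(w1, w2, w3))
        parts = sum(
            cp_reconstruct(CPNeuronFactors(w1[k:k + 1], w2[k:k + 1], w3[k:k + 1]))
            for k in range(2)
        )
        np.testing.assert_allclose(full, parts, atol=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        f = CPNeuronFactors(rng.normal(size=(3, 6)), rng.normal(size=(3, 6)),
                            rng.normal(size=(3, 4)))
        np.testing.assert_allclose(cp_reconstruct(f), brute_force_reconstruct(f),
                                   rtol=1e-12)


class TestHiddenPreactivation:
    def test_zero_input_gives_zero(self):
        rng = np.random.default_rng(3)
        f = CPNeuronFactors(rng.normal(size=(2, 5)), rng.normal(size=(2, 5)),
                            rng.normal(size=(2, 3)))
        assert hidden_preactivation(f, np.zeros((5, 5, 3))) == 0.0

    def test_all_ones_sums_entries(self):
        f = CPNeuronFactors(np.ones((1, 3)), np.ones((1, 3)), np.ones((1, 2)))
        assert hidden_preactivation(f, np.ones((3, 3, 2))) == pytest.approx(18.0)

    def test_matches_materialized_inner_product(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            f = CPNeuronFactors(rng.normal(size=(4, 7)), rng.normal(size=(4, 7)),
                                rng.normal(size=(4, 10)))
            X = rng.normal(size=(7, 7, 10))
            expect = float((cp_reconstruct(f) * X).sum())
            got = hidden_preactivation(f, X)
            assert got == pytest.approx(expect, rel=1e-8)

    def test_dimension_mismatch_names_axis(self):
        f = CPNeuronFactors(np.ones((1, 5)), np.ones((1, 5)), np.ones((1, 3)))
        with pytest.raises(ValueError, match="axis 1"):
            hidden_preactivation(f, np.zeros((5, 4, 3)))


class TestForwardPredict:
    dims = ModelDims(s=5, b=4, C=3, Q=6, R=2)

    def test_zero_parameters_give_uniform_probabilities(self):
        p = init_params(self.dims, seed=0)
        for name in ("W1", "W2", "W3", "V"):
            getattr(p, name)[:] = 0.0
        probs = forward(p, np.random.default_rng(0).normal(size=(5, 5, 4)))
        np.testing.assert_allclose(probs, [1 / 3] * 3, atol=1e-12)

    def test_logit_shift_invariance(self):
        rng = np.random.default_rng(5)
        p = init_params(self.dims, seed=1)
        X = rng.normal(size=(5, 5, 4))
        base = forward(p, X)
        shifted = p.copy()
        shifted.V += rng.normal(size=self.dims.Q)  # same shift for every class row
        np.testing.assert_allclose(forward(shifted, X), base, atol=1e-9)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(6)
        p = init_params(self.dims, seed=2)
        X = rng.normal(size=(50, 5, 5, 4))
        probs = forward(p, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs > 0).all()

    def test_predict_is_onehot_argmax_of_forward(self):
        rng = np.random.default_rng(7)
        p = init_params(self.dims, seed=3)
        X = rng.normal(size=(100, 5, 5, 4))
        probs = forward(p, X)
        preds = predict(p, X)
        assert (preds.sum(axis=1) == 1).all()
        np.testing.assert_array_equal(preds.argmax(axis=1), probs.argmax(axis=1))

    def test_tie_breaks_to_lowest_class(self):
        p = init_params(self.dims, seed=0)
        for name in ("W1", "W2", "W3", "V"):
            getattr(p, name)[:] = 0.0  # uniform probabilities = exact tie
        pred = predict(p, np.ones((5, 5, 4)))
        np.testing.assert_array_equal(pred, [1.0, 0.0, 0.0])

    def test_chunked_forward_matches_direct(self):
        rng = np.random.default_rng(8)
        p = init_params(self.dims, seed=4)
        X = rng.normal(size=(700, 5, 5, 4))
        np.testing.assert_allclose(forward(p, X, chunk=128), forward(p, X, chunk=1000),
                                   rtol=1e-12)


def test_cross_entropy_equals_neg_log_true_prob():
    p = np.array([[0.2, 0.5, 0.3]])
    t = np.array([[0.0, 1.0, 0.0]])
    assert cross_entropy(p, t) == -np.log(0.5)


class TestGradients:
    def test_manual_gradients_match_finite_differences(self):
        dims = ModelDims(s=3, b=2, C=3, Q=2, R=2)
        rng = np.random.default_rng(10)
        params = init_params(dims, seed=11, activation="sigmoid")
        X = rng.normal(size=(1, 3, 3, 2))
        T = np.array([[0.0, 1.0, 0.0]])
        _, grads = loss_and_grads(params, X, T)
        h = 1e-6
        worst = 0.0
        for name in ("W1", "W2", "W3", "V"):
            arr = getattr(params, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + h
                lp, _ = loss_and_grads(params, X, T)
                arr[i] = orig - h
                lm, _ = loss_and_grads(params, X, T)
                arr[i] = orig
                fd = (lp - lm) / (2 * h)
                g = grads[name][i]
                worst = max(worst, abs(fd - g) / max(abs(fd), abs(g), 1e-8))
        assert worst < 1e-5

    def test_gradient_flows_to_every_parameter(self):
        dims = ModelDims(s=5, b=3, C=3, Q=4, R=2)
        rng = np.random.default_rng(12)
        params = init_params(dims, seed=13, activation="sigmoid")
        X = rng.normal(size=(20, 5, 5, 3))
        T = np.zeros((20, 3))
        T[np.arange(20), rng.integers(0, 3, 20)] = 1
        _, grads = loss_and_grads(params, X, T)
        for name in ("W1", "W2", "W3", "V"):
            assert (grads[name] != 0).any(), name


def make_separable(n_per_class=50, s=7, b=3, shift=3.0, seed=0):
    """Tensors whose class means differ by `shift` standard deviations along
    a fixed rank-1 pattern, so a linear rule suffices."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=s)
    v = rng.normal(size=s)
    w = rng.normal(size=b)
    pattern = np.einsum("i,j,k->ijk", u, v, w)
    pattern /= np.linalg.norm(pattern)
    X, T = [], []
    for c in range(3):
        X.append(rng.normal(size=(n_per_class, s, s, b)) + (c - 1) * shift * pattern)
        t = np.zeros((n_per_class, 3))
        t[:, c] = 1
        T.append(t)
    return np.concatenate(X), np.concatenate(T)


class TestTraining:
    def test_zero_epochs_returns_seeded_initialization(self):
        dims = ModelDims(s=5, b=3, C=3, Q=4, R=2)
        X, T = make_separable(10, 5, 3)
        cfg = TrainConfig(epochs=0, eval_every=0, seed=42)
        p1, h1 = fit_arrays(X, T, dims, cfg)
        p2, _ = fit_arrays(X, T, dims, cfg)
        assert h1.train_loss == []
        for name in ("W1", "W2", "W3", "V"):
            np.testing.assert_array_equal(getattr(p1, name), getattr(p2, name))
        # equals the initialization drawn from the config-derived seed
        derived = int(np.random.default_rng(42).integers(2**31 - 1))
        init = init_params(dims, seed=derived, activation=cfg.activation)
        np.testing.assert_array_equal(p1.W1, init.W1)

    def test_learns_linearly_separable_tensors(self):
        X, T = make_separable(50, 7, 3, shift=3.0, seed=1)
        dims = ModelDims(s=7, b=3, C=3, Q=8, R=2)
        cfg = TrainConfig(epochs=70, eval_every=70, seed=0, batch_size=8)
        params, history = fit_arrays(X, T, dims, cfg)
        acc = (predict(params, X).argmax(1) == T.argmax(1)).mean()
        assert acc >= 0.95
        assert history.train_loss[-1] < history.train_loss[0]

    def test_seeded_determinism_of_history(self):
        X, T = make_separable(20, 5, 3, seed=2)
        dims = ModelDims(s=5, b=3, C=3, Q=4, R=2)
        cfg = TrainConfig(epochs=8, eval_every=4, seed=9)
        _, h1 = fit_arrays(X, T, dims, cfg, X, T)
        _, h2 = fit_arrays(X, T, dims, cfg, X, T)
        assert h1.train_loss == h2.train_loss
        assert h1.test_accuracy == h2.test_accuracy
        assert h1.test_macro_f1 == h2.test_macro_f1


class TestCountParameters:
    def test_paper_scale_dimensions(self):
        fact, dense = count_parameters(ModelDims(s=35, b=10, C=3, Q=50, R=8))
        assert (fact, dense) == (32150, 612650)
        assert fact / dense < 0.06

    def test_tiny_dimensions(self):
        fact, dense = count_parameters(ModelDims(s=3, b=1, C=2, Q=1, R=1))
        assert (fact, dense) == (9, 11)

    def test_counts_match_stored_scalar_enumeration(self):
        dims = ModelDims(s=9, b=10, C=3, Q=7, R=3)
        fact, dense = count_parameters(dims)
        params = init_params(dims)
        stored = sum(getattr(params, n).size for n in ("W1", "W2", "W3", "V"))
        assert fact == stored
        dense_stored = dims.Q * dims.s * dims.s * dims.b + params.V.size
        assert dense == dense_stored

    def test_warns_when_rank_too_high_to_save(self):
        with pytest.warns(UserWarning, match="rank"):
            count_parameters(ModelDims(s=3, b=2, C=2, Q=2, R=5))
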