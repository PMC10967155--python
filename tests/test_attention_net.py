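"""Attention network: closed-form layer checks, gradient check, training."""

import numpy as np
import pytest

from dsccn.attention_net import (
    AttentionNetClassifier,
    NetConfig,
    _backward_full,
    _forward_full,
    _tree_leaves,
    attended_modules,
    attention_matrix,
    encode_modules,
    forward,
    hyperparameter_search,
    init_params,
    loss,
    train,
)
from dsccn.synthetic import (
    CanonicalPairSpec,
    SubtypeSpec,
    generate_subtyped_dataset,
)


def tiny_config(**kw):
    base = dict(n_modules=(2, 3), module_dim=2, n_classes=3, hidden_sizes=(4,),
                activation="tanh")
    base.update(kw)
    return NetConfig(**base)


@pytest.fixture(scope="module")
def separable_views():
    pair = CanonicalPairSpec.with_block_supports(
        s=400, m=20, n=20, k_u=8, k_v=8, latent_corr=0.9, noise_sd=0.5, seed=5
    )
    sub = SubtypeSpec(class_sizes=(100, 100, 100, 100), class_shift=2.5, seed=5)
    ds = generate_subtyped_dataset(pair, sub, n_healthy=10).disease_view()
    return [ds.X.values, ds.Y.values], ds.subtype.values.astype(str)


class TestEncoder:
    def test_zero_params_give_zero_modules(self):
        cfg = tiny_config(activation="identity")
        params = init_params(cfg, (4, 5), np.random.default_rng(0))
        params["enc"][0]["W"][:] = 0.0
        M = encode_modules(np.ones(4), 0, params, cfg)
        assert M.shape == (2, 2)
        assert np.all(M == 0)

    def test_hand_computed_module(self):
        cfg = NetConfig(n_modules=(1, 1), module_dim=2, n_classes=2,
                        activation="identity")
        params = init_params(cfg, (2, 2), np.random.default_rng(0))
        params["enc"][0]["W"] = np.array([[1.0, 0.0], [0.0, 1.0]])
        params["enc"][0]["b"][:] = 0.0
        M = encode_modules(np.array([1.0, 1.0]), 0, params, cfg)
        assert np.allclose(M, [[1.0, 1.0]])

    def test_output_shape_contract(self):
        cfg = NetConfig(n_modules=(16, 4), module_dim=8, n_classes=2)
        params = init_params(cfg, (30, 10), np.random.default_rng(1))
        M = encode_modules(np.random.default_rng(2).normal(size=30), 0,
                           params, cfg)
        assert M.shape == (16, 8)

    def test_feature_mismatch_rejected(self):
        cfg = tiny_config()
        params = init_params(cfg, (4, 5), np.random.default_rng(0))
        with pytest.raises(ValueError):
            encode_modules(np.ones(7), 0, params, cfg)


class TestAttention:
    def test_identical_target_rows_give_uniform_rows(self):
        rng = np.random.default_rng(0)
        M_i = rng.normal(size=(4, 3))
        M_j = np.tile(rng.normal(size=(1, 3)), (5, 1))
        att = attention_matrix(M_i, M_j)
        assert np.allclose(att, 1 / 5)

    def test_scalar_softmax_of_opposite_cosines(self):
        M_i = np.array([[1.0, 0.0]])
        M_j = np.array([[2.0, 0.0], [-3.0, 0.0]])  # cosines (1, -1)
        att = attention_matrix(M_i, M_j)
        expect = np.exp([1.0, -1.0])
        expect /= expect.sum()
        assert np.allclose(att[0], expect, atol=1e-4)

    def test_rows_sum_to_one_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            att = attention_matrix(rng.normal(size=(6, 4)),
                                   rng.normal(size=(9, 4)))
            assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)
            assert np.all((att > 0) & (att < 1))

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(4)
        M_i, M_j = rng.normal(size=(3, 5)), rng.normal(size=(4, 5))
        a = attention_matrix(M_i, M_j)
        M_i2 = M_i.copy()
        M_i2[1] *= 7.3
        assert np.allclose(a, attention_matrix(M_i2, M_j), atol=1e-12)

    def test_zero_norm_row_rejected(self):
        M = np.ones((2, 3))
        M[1] = 0.0
        with pytest.raises(ValueError, match="zero-norm module row 1"):
            attention_matrix(M, np.ones((2, 3)))

    def test_uniform_attention_averages_modules(self):
        rng = np.random.default_rng(5)
        M_j = rng.normal(size=(4, 3))
        M_other = np.tile(rng.normal(size=(1, 3)), (4, 1))
        out = attended_modules(M_j, M_other)
        assert np.allclose(out, np.tile(M_j.mean(axis=0), (4, 1)))

    def test_single_module_passthrough(self):
        M_j = np.array([[1.0, 2.0, 3.0]])
        out = attended_modules(M_j, np.array([[4.0, 5.0, 6.0]]))
        assert np.allclose(out, M_j)

    def test_attended_product_matches_naive_loops(self):
        rng = np.random.default_rng(6)
        M_j, M_o = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        att = attention_matrix(M_j, M_o)
        naive = np.zeros((5, 4))
        for k in range(5):
            for l in range(3):
                naive[k] += att[l, k] * M_j[l]
        assert np.allclose(attended_modules(M_j, M_o), naive, atol=1e-10)


class TestForwardAndLoss:
    def test_probabilities_are_row_stochastic(self):
        cfg = tiny_config()
        params = init_params(cfg, (4, 5), np.random.default_rng(0))
        rng = np.random.default_rng(1)
        out = forward(rng.normal(size=(7, 4)), rng.normal(size=(7, 5)),
                      params, cfg)
        assert out.shape == (7, 2, 3)
        assert np.allclose(out.sum(axis=2), 1.0, atol=1e-6)
        assert np.all(out >= 0)

    def test_zero_logits_give_uniform_binary(self):
        cfg = NetConfig(n_modules=(1, 1), module_dim=2, n_classes=2,
                        hidden_sizes=(), activation="identity")
        params = init_params(cfg, (2, 2), np.random.default_rng(0))
        for head in params["heads"]:
            for layer in head:
                layer["W"][:] = 0.0
        out = forward(np.ones(2), np.ones(2), params, cfg)
        assert np.allclose(out, 0.5)

    def test_loss_examples(self):
        assert loss([0], [np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]])]) == 0.0
        got = loss([0], [np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])])
        assert np.isclose(got, 2 * np.log(2))

    def test_loss_nonnegative_and_validates_probs(self):
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(3), size=6)
        assert loss(rng.integers(0, 3, 6), [P, P]) >= 0
        with pytest.raises(ValueError):
            loss([0], [np.array([[1.5, -0.5]])])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = tiny_config()
        rng = np.random.default_rng(0)
        xs = [rng.standard_normal((3, 4)), rng.standard_normal((3, 5))]
        y = np.array([0, 2, 1])
        onehot = np.eye(3)[y]
        params = init_params(cfg, (4, 5), rng)
        probs, cache = _forward_full(xs, params, cfg)
        grads = _backward_full(xs, onehot, probs, cache, params, cfg)

        def f():
            pr, _ = _forward_full(xs, params, cfg)
            return loss(y, pr)

        eps = 1e-6
        rng2 = np.random.default_rng(1)
        for pl, gl in zip(_tree_leaves(params), _tree_leaves(grads)):
            for key in pl:
                arr = pl[key]
                flat = arr.reshape(-1)
                for idx in rng2.choice(flat.size, size=min(6, flat.size),
                                       replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = f()
                    flat[idx] = orig - eps
                    lm = f()
                    flat[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = gl[key].reshape(-1)[idx]
                    assert abs(num - ana) <= 1e-6 * max(1.0, abs(num))

    def test_gradcheck_without_attention(self):
        cfg = tiny_config(attention=False)
        rng = np.random.default_rng(0)
        xs = [rng.standard_normal((4, 4)), rng.standard_normal((4, 5))]
        y = np.array([0, 1, 2, 0])
        params = init_params(cfg, (4, 5), rng)
        probs, cache = _forward_full(xs, params, cfg)
        grads = _backward_full(xs, np.eye(3)[y], probs, cache, params, cfg)
        W = params["enc"][0]["W"]
        eps = 1e-6
        orig = W[0, 0]
        W[0, 0] = orig + eps
        lp = loss(y, _forward_full(xs, params, cfg)[0])
        W[0, 0] = orig - eps
        lm = loss(y, _forward_full(xs, params, cfg)[0])
        W[0, 0] = orig
        assert np.isclose((lp - lm) / (2 * eps), grads["enc"][0]["W"][0, 0],
                          atol=1e-7)


class TestTraining:
    def test_separable_data_reaches_high_accuracy(self, separable_views):
        views, y = separable_views
        from sklearn.model_selection import train_test_split
        idx = np.arange(len(y))
        tr, te = train_test_split(idx, test_size=0.3, stratify=y,
                                  random_state=0)
        clf = AttentionNetClassifier(n_modules=(16, 16), max_epochs=150,
                                     patience=30, seed=0)
        clf.fit([v[tr] for v in views], y[tr])
        acc = np.mean(clf.predict([v[te] for v in views]) == y[te])
        assert acc >= 0.9

    def test_loss_decreases_early(self, separable_views):
        views, y = separable_views
        clf = AttentionNetClassifier(n_modules=(8, 8), max_epochs=10,
                                     patience=10, seed=0)
        clf.fit(views, y)
        tr_losses = [h[0] for h in clf.train_history_]
        assert tr_losses[-1] < tr_losses[0]

    def test_zero_learning_rate_freezes_parameters(self, separable_views):
        views, y = separable_views
        clf = AttentionNetClassifier(n_modules=(4, 4), learning_rate=0.0,
                                     max_epochs=5, patience=5, seed=3)
        clf.fit(views, y)
        losses = [h[0] for h in clf.train_history_]
        assert np.allclose(losses, losses[0])
        # weights equal the seeded initialisation
        cfg = clf.config_
        fresh = init_params(cfg, clf.n_features_in_,
                            np.random.default_rng(cfg.seed))
        assert np.allclose(clf.params_["enc"][0]["W"], fresh["enc"][0]["W"])

    def test_same_seed_reproduces_history(self, separable_views):
        views, y = separable_views
        kw = dict(n_modules=(4, 4), max_epochs=8, patience=8, seed=9)
        a = AttentionNetClassifier(**kw).fit(views, y)
        b = AttentionNetClassifier(**kw).fit(views, y)
        assert a.train_history_ == b.train_history_

    def test_early_stopping_respects_patience(self, separable_views):
        views, y = separable_views
        clf = AttentionNetClassifier(n_modules=(4, 4), max_epochs=300,
                                     patience=10, seed=0)
        clf.fit(views, y)
        assert len(clf.train_history_) <= clf.best_epoch_ + 10

    def test_attention_toggle_keeps_encoder_shape(self):
        cfg_on = tiny_config(attention=True)
        cfg_off = tiny_config(attention=False)
        rng = np.random.default_rng(0)
        p_on = init_params(cfg_on, (4, 5), rng)
        p_off = init_params(cfg_off, (4, 5), np.random.default_rng(0))
        for a, b in zip(p_on["enc"], p_off["enc"]):
            assert a["W"].shape == b["W"].shape

    def test_save_load_roundtrip(self, separable_views, tmp_path):
        views, y = separable_views
        clf = AttentionNetClassifier(n_modules=(4, 4), max_epochs=5,
                                     patience=5, seed=1)
        clf.fit(views, y)
        path = tmp_path / "model.npz"
        clf.save(path)
        again = AttentionNetClassifier.load(path)
        a = clf.predict_proba(views)
        b = again.predict_proba(views)
        assert np.allclose(a, b)

    def test_train_wrapper_and_predict(self, separable_views):
        views, y = separable_views
        cfg = NetConfig(n_modules=(4, 4), n_classes=4, max_epochs=5,
                        patience=5, seed=0)
        model = train(views, y, cfg)
        from dsccn.attention_net import predict
        fused, per_task = predict(model, views[0][:3], views[1][:3])
        assert fused.shape == (3, 4)
        assert per_task.shape == (3, 2, 4)
        assert np.allclose(fused, per_task.mean(axis=1))


class TestHyperparameterSearch:
    def test_single_cell_grid_returned(self, separable_views):
        views, y = separable_views
        base = NetConfig(n_modules=(4, 4), n_classes=4, max_epochs=3,
                         patience=3, seed=0)
        cfg = hyperparameter_search(views, y, {"weight_decay": [1e-4]},
                                    base=base)
        assert cfg.weight_decay == 1e-4

    def test_zero_lr_candidate_loses_on_separable_data(self, separable_views):
        views, y = separable_views
        base = NetConfig(n_modules=(8, 8), n_classes=4, max_epochs=25,
                         patience=25, seed=0)
        cfg = hyperparameter_search(
            views, y, {"learning_rate": [0.0, 1e-3]}, base=base
        )
        assert cfg.learning_rate == 1e-3

    def test_empty_grid_rejected(self, separable_views):
        views, y = separable_views
        with pytest.raises(ValueError):
            hyperparameter_search(views, y, {"learning_rate": []})
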