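"""Squashing, dynamic routing and the capsule classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedcaps.capsules import (
    CapsuleNet,
    ClassifierConfig,
    build_classifier,
    deep_features,
    dynamic_routing,
    margin_loss,
    predict,
    squash,
    squash_backward,
    train_classifier,
)


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert np.allclose(squash(np.zeros(5)), 0.0)

    def test_unit_norm_halved(self):
        v = squash(np.array([1.0, 0.0, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(0.5, abs=1e-9)

    def test_long_vector_saturates_below_one(self):
        s = np.array([1000.0, 0.0])
        n = np.linalg.norm(squash(s))
        assert 0.999998 <= n < 1.0

    def test_direction_preserved(self, rng):
        s = rng.normal(size=6)
        v = squash(s)
        cos = v @ s / (np.linalg.norm(v) * np.linalg.norm(s))
        assert cos == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0.01, 50.0), st.floats(0.01, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_norm_strictly_increasing_and_bounded(self, n1, n2):
        lo, hi = sorted([n1, n2])
        e = np.array([1.0, 0.0])
        vlo = np.linalg.norm(squash(lo * e))
        vhi = np.linalg.norm(squash(hi * e))
        assert vhi < 1.0
        if hi > lo:
            assert vhi > vlo

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            squash(np.array([np.nan, 1.0]))


class TestRouting:
    def test_single_parent_couplings_are_one(self, rng):
        u_hat = rng.normal(size=(2, 4, 1, 3))
        _, c = dynamic_routing(u_hat, iters=3)
        assert np.allclose(c, 1.0)

    def test_zero_predictions_give_zero_parents(self):
        v, _ = dynamic_routing(np.zeros((1, 3, 2, 4)), iters=3)
        assert np.allclose(v, 0.0)

    def test_agreeing_parent_coupling_strictly_increases(self):
        u_hat = np.zeros((1, 2, 2, 3))
        u_hat[0, :, 0, :] = [[1, 0, 0], [1, 0, 0]]   # both agree with parent 0
        u_hat[0, :, 1, :] = [[0.3, 0.2, -0.1], [-0.2, 0.1, 0.3]]
        cs = [dynamic_routing(u_hat, it)[1][0, 0, 0] for it in (1, 2, 3)]
        assert np.all(np.diff(cs) > 0)

    def test_couplings_are_distribution_over_parents(self, rng):
        u_hat = rng.normal(size=(2, 5, 3, 4))
        for it in (1, 2, 4):
            _, c = dynamic_routing(u_hat, it)
            assert np.allclose(c.sum(axis=2), 1.0)
            assert np.all(c >= 0)

    def test_output_norms_below_one(self, rng):
        v, _ = dynamic_routing(10 * rng.normal(size=(3, 6, 2, 4)), iters=3)
        assert np.all(np.sqrt((v**2).sum(-1)) < 1.0)


class TestGradients:
    def test_margin_loss_through_squash_numeric_check(self, rng):
        """Analytic vs numeric gradient on a 3-dim toy, 1e-4 relative."""
        s0 = rng.normal(size=(1, 2, 3))
        t = np.array([[1.0, 0.0]])

        def loss_of(sx):
            return margin_loss(squash(sx), t)[0]

        _, dv = margin_loss(squash(s0), t)
        ds = squash_backward(dv, s0)
        eps = 1e-6
        for idx in np.ndindex(s0.shape):
            sp, sm = s0.copy(), s0.copy()
            sp[idx] += eps
            sm[idx] -= eps
            num = (loss_of(sp) - loss_of(sm)) / (2 * eps)
            assert abs(num - ds[idx]) <= 1e-4 * max(abs(num), 1e-6)

    def test_whole_net_gradient_exact_with_one_routing_iter(self, rng):
        cfg = ClassifierConfig(mode="features", in_dim=6, n_primary=3,
                               primary_dim=4, digit_dim=4, routing_iters=1, seed=0)
        net = build_classifier(cfg)
        X = rng.normal(size=(4, 6))
        oh = np.eye(2)[np.array([0, 1, 0, 1])]

        def full_loss():
            return margin_loss(net.forward(X, True), oh)[0]

        v = net.forward(X, True)
        _, dv = margin_loss(v, oh)
        net.zero_grad()
        net.backward(dv)
        g = net.grad_flat()
        w = net.get_flat()
        for i in rng.choice(w.size, 25, replace=False):
            w2 = w.copy()
            w2[i] += 1e-6
            net.set_flat(w2)
            lp = full_loss()
            w2[i] -= 2e-6
            net.set_flat(w2)
            lm = full_loss()
            assert g[i] == pytest.approx((lp - lm) / 2e-6, abs=1e-6)
        net.set_flat(w)


@pytest.fixture(scope="module")
def separable_features():
    rng = np.random.default_rng(0)
    n = 40
    X = np.vstack([rng.normal(0, 1, (n, 8)), rng.normal(2, 1, (n, 8))])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestTrainClassifier:
    def test_zero_epochs_returns_initialization(self, separable_features):
        X, y = separable_features
        cfg = ClassifierConfig(mode="features", in_dim=8, seed=2)
        init = build_classifier(cfg).get_flat()
        model, history = train_classifier(X, y, cfg, epochs=0)
        assert np.array_equal(model.get_flat(), init)
        assert history == []

    def test_overfits_eight_samples_quickly(self, separable_features):
        X, y = separable_features
        idx = [0, 1, 2, 3, 76, 77, 78, 79]
        model, history = train_classifier(
            X[idx], y[idx],
            ClassifierConfig(mode="features", in_dim=8, seed=1),
            epochs=100, lr=1e-3, batch_size=8, seed=1,
        )
        assert history[-1]["accuracy"] == 1.0

    def test_full_batch_loss_non_increasing_early(self, separable_features):
        X, y = separable_features
        _, history = train_classifier(
            X, y, ClassifierConfig(mode="features", in_dim=8, seed=0),
            epochs=10, lr=1e-3, batch_size=len(y), seed=0,
        )
        losses = [h["loss"] for h in history]
        assert all(np.isfinite(losses))
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_deterministic_under_seed(self, separable_features):
        X, y = separable_features
        cfg = ClassifierConfig(mode="features", in_dim=8, seed=0)
        m1, h1 = train_classifier(X, y, cfg, epochs=3, seed=5)
        m2, h2 = train_classifier(X, y, cfg, epochs=3, seed=5)
        assert np.array_equal(m1.get_flat(), m2.get_flat())
        assert h1 == h2

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_classifier(rng.normal(size=(10, 4)), np.zeros(10, dtype=int))


class TestPredict:
    def test_confidences_in_unit_interval(self, separable_features):
        X, _ = separable_features
        model = build_classifier(ClassifierConfig(mode="features", in_dim=8, seed=0))
        _, conf = predict(model, X)
        assert np.all((conf >= 0) & (conf < 1))

    def test_untrained_model_deterministic(self, separable_features):
        X, _ = separable_features
        cfg = ClassifierConfig(mode="features", in_dim=8, seed=3)
        l1, c1 = predict(build_classifier(cfg), X)
        l2, c2 = predict(build_classifier(cfg), X)
        assert np.array_equal(l1, l2) and np.array_equal(c1, c2)

    def test_predicted_positive_rate_tracks_prevalence(self, separable_features):
        X, y = separable_features
        model, _ = train_classifier(
            X, y, ClassifierConfig(mode="features", in_dim=8, seed=0),
            epochs=20, seed=0,
        )
        labels, _ = predict(model, X)
        assert abs(labels.mean() - y.mean()) <= 0.10

    def test_single_feature_vector_input(self, separable_features):
        X, _ = separable_features
        model = build_classifier(ClassifierConfig(mode="features", in_dim=8, seed=0))
        label, conf = predict(model, X[0])
        assert conf.shape == (2,) and label in (0, 1)


class TestImageMode:
    def test_backbone_path_and_deep_features(self, small_dataset):
        scans = small_dataset[:4] + small_dataset[-4:]  # tumor + no-tumor mix
        model, history = train_classifier(
            scans, config=ClassifierConfig(mode="image", seed=0),
            epochs=1, batch_size=4, seed=0,
        )
        assert np.isfinite(history[-1]["loss"])
        feats = deep_features(model, scans[0].image)
        assert feats.shape == (32,)
        label, conf = predict(model, scans[0].image)
        assert conf.shape == (2,)

    def test_feature_mode_has_no_deep_features(self):
        model = build_classifier(ClassifierConfig(mode="features", in_dim=4))
        with pytest.raises(ValueError):
            deep_features(model, np.zeros((64, 64)))
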