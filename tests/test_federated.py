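"""FedAvg aggregation, failure injection, DP noise and the round loop."""

import inspect

import numpy as np
import pytest

from fedcaps.capsules import ClassifierConfig, build_classifier
from fedcaps.federated import (
    ClientUpdate,
    DPConfig,
    FLConfig,
    dp_noise,
    fedavg,
    inject_failures,
    local_train,
    run_simulation,
    train_centralized,
)
from fedcaps.ledger import verify_chain


def mk_update(cid, w, n=1, rnd=0):
    return ClientUpdate(client_id=cid, round=rnd, n_k=n, weights=np.asarray(w, float))


class TestFedAvg:
    def test_single_client_identity(self, rng):
        w = rng.normal(size=20)
        assert np.array_equal(fedavg([mk_update("a", w)]), w)

    def test_equal_counts_arithmetic_mean(self, rng):
        w1, w2 = rng.normal(size=10), rng.normal(size=10)
        out = fedavg([mk_update("a", w1), mk_update("b", w2)])
        assert np.allclose(out, (w1 + w2) / 2)

    def test_weighted_scalar_example(self):
        out = fedavg([mk_update("a", [1.0], n=1), mk_update("b", [5.0], n=3)])
        assert out[0] == pytest.approx(4.0)

    def test_linearity_in_updates(self, rng):
        ws = [rng.normal(size=8) for _ in range(3)]
        ups = [mk_update(f"c{i}", w, n=i + 1) for i, w in enumerate(ws)]
        scaled = [mk_update(f"c{i}", 2 * w, n=i + 1) for i, w in enumerate(ws)]
        assert np.allclose(fedavg(scaled), 2 * fedavg(ups))

    def test_order_invariance(self, rng):
        ups = [mk_update(f"c{i}", rng.normal(size=50), n=i + 1) for i in range(5)]
        base = fedavg(ups)
        for _ in range(5):
            perm = [ups[i] for i in rng.permutation(5)]
            assert np.max(np.abs(fedavg(perm) - base)) < 1e-9

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            fedavg([])
        with pytest.raises(ValueError):
            fedavg([mk_update("a", [1.0]), mk_update("b", [1.0, 2.0])])


@pytest.fixture(scope="module")
def feature_clients():
    rng = np.random.default_rng(7)
    data = {}
    for i in range(3):
        n = 30
        X = np.vstack([rng.normal(0, 1, (n, 6)), rng.normal(2, 1, (n, 6))])
        y = np.array([0] * n + [1] * n)
        data[f"client-{i+1}"] = (X, y)
    Xe = np.vstack([rng.normal(0, 1, (20, 6)), rng.normal(2, 1, (20, 6))])
    ye = np.array([0] * 20 + [1] * 20)
    return data, (Xe, ye)


def clf_factory():
    return build_classifier(ClassifierConfig(mode="features", in_dim=6, seed=0))


class TestLocalTrain:
    def test_zero_epochs_returns_global(self, feature_clients):
        data, _ = feature_clients
        g = clf_factory().get_flat()
        upd = local_train(data["client-1"], g, clf_factory, "client-1", 0,
                          local_epochs=0)
        assert np.array_equal(upd.weights, g)

    def test_sample_count_recorded(self, feature_clients):
        data, _ = feature_clients
        g = clf_factory().get_flat()
        upd = local_train(data["client-2"], g, clf_factory, "client-2", 0,
                          local_epochs=1)
        assert upd.n_k == len(data["client-2"][1])

    def test_identical_clients_identical_updates(self, feature_clients):
        data, _ = feature_clients
        g = clf_factory().get_flat()
        u1 = local_train(data["client-1"], g, clf_factory, "same-id", 3,
                         local_epochs=2, seed=1)
        u2 = local_train(data["client-1"], g, clf_factory, "same-id", 3,
                         local_epochs=2, seed=1)
        assert np.array_equal(u1.weights, u2.weights)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            local_train((np.zeros((0, 4)), np.zeros(0)), np.zeros(10),
                        clf_factory, "c", 0)


class TestInjectFailures:
    def test_zero_rates_pass_through(self, rng):
        ups = [mk_update(f"c{i}", rng.normal(size=5)) for i in range(4)]
        out, log = inject_failures(ups, 0.0, 0.0, 0.5, rng)
        assert [u.client_id for u in out] == [u.client_id for u in ups]
        assert not log["dropped"] and not log["poisoned"]

    def test_total_dropout_empties_round(self, rng):
        ups = [mk_update("a", np.ones(3)), mk_update("b", np.ones(3))]
        out, log = inject_failures(ups, 1.0, 0.0, 0.5, rng)
        assert out == [] and set(log["dropped"]) == {"a", "b"}

    def test_empirical_dropout_rate(self):
        rng = np.random.default_rng(0)
        dropped = 0
        trials = 10_000
        for _ in range(trials):
            out, _ = inject_failures([mk_update("a", np.ones(2))], 0.10, 0.0,
                                     0.5, rng)
            dropped += not out
        assert abs(dropped / trials - 0.10) <= 0.01

    def test_poisoning_perturbs_weights(self):
        rng = np.random.default_rng(1)
        w = np.ones(100)
        out, log = inject_failures([mk_update("a", w)], 0.0, 1.0, 0.5, rng)
        assert log["poisoned"] == ["a"]
        noise = out[0].weights - w
        assert noise.std() == pytest.approx(0.5, rel=0.3)  # sigma = 0.5*RMS(1)


class TestDPNoise:
    def test_clipping_bounds_l2_norm(self, rng):
        upd = mk_update("a", 10 * rng.normal(size=50))
        out = dp_noise(upd, epsilon=np.inf, delta=1e-5, clip_norm=1.0, rng=rng)
        assert np.linalg.norm(out.weights) <= 1.0 + 1e-12

    def test_noiseless_mode_preserves_preclipped(self, rng):
        w = np.ones(10) * 0.01
        out = dp_noise(mk_update("a", w), np.inf, 1e-5, 1.0, rng)
        assert np.array_equal(out.weights, w)

    def test_noise_std_matches_gaussian_mechanism(self):
        rng = np.random.default_rng(0)
        eps, delta, clip = 1.0, 1e-5, 1.0
        w = np.zeros(10_000)
        out = dp_noise(mk_update("a", w), eps, delta, clip, rng)
        sigma = clip * np.sqrt(2 * np.log(1.25 / delta)) / eps
        assert out.weights.std() == pytest.approx(sigma, rel=0.05)

    def test_invalid_epsilon_rejected(self, rng):
        with pytest.raises(ValueError):
            dp_noise(mk_update("a", np.ones(3)), 0.0, 1e-5, 1.0, rng)
        with pytest.raises(ValueError):
            DPConfig(enabled=True, epsilon=-1.0)


class TestRunSimulation:
    def test_single_client_matches_centralized_bitwise(self, feature_clients):
        data, eval_set = feature_clients
        single = {"client-1": data["client-1"]}
        cfg = FLConfig(rounds=4, local_epochs=2, dropout_rate=0.0,
                       noise_rate=0.0, seed=0)
        _, w_fl, _ = run_simulation(cfg, single, clf_factory, eval_set)
        w_c = train_centralized(data["client-1"], clf_factory, rounds=4,
                                local_epochs=2, lr=cfg.lr, seed=0,
                                client_id="client-1")
        assert np.array_equal(w_fl, w_c)

    def test_same_seed_identical_round_digests(self, feature_clients):
        data, eval_set = feature_clients
        cfg = FLConfig(rounds=3, local_epochs=1, dropout_rate=0.2,
                       noise_rate=0.2, seed=11)
        h1, _, _ = run_simulation(cfg, data, clf_factory, eval_set)
        h2, _, _ = run_simulation(cfg, data, clf_factory, eval_set)
        assert [r.global_digest for r in h1] == [r.global_digest for r in h2]

    def test_total_dropout_round_skipped_and_global_retained(self, feature_clients):
        data, eval_set = feature_clients
        cfg = FLConfig(rounds=2, local_epochs=1, dropout_rate=1.0,
                       noise_rate=0.0, seed=0)
        history, w, ledger = run_simulation(cfg, data, clf_factory, eval_set)
        assert all(r.eval_metrics.get("skipped") for r in history)
        assert np.array_equal(w, clf_factory().get_flat())
        assert len(ledger.chain) == 0

    def test_ledger_chain_valid_after_run(self, feature_clients):
        data, eval_set = feature_clients
        cfg = FLConfig(rounds=3, local_epochs=1, dropout_rate=0.0,
                       noise_rate=0.0, seed=0)
        _, _, ledger = run_simulation(cfg, data, clf_factory, eval_set)
        assert len(ledger.chain) == 3
        assert verify_chain(ledger)["valid"]

    def test_dp_round_still_learns_structure(self, feature_clients):
        data, eval_set = feature_clients
        cfg = FLConfig(rounds=3, local_epochs=2, dropout_rate=0.0,
                       noise_rate=0.0, seed=0,
                       dp=DPConfig(enabled=True, epsilon=50.0, clip_norm=50.0))
        history, _, _ = run_simulation(cfg, data, clf_factory, eval_set)
        assert "accuracy" in history[-1].eval_metrics


class TestRawDataIsolation:
    """The aggregation boundary carries model updates only, never data."""

    def test_fedavg_signature_accepts_updates_only(self):
        params = inspect.signature(fedavg).parameters
        assert list(params) == ["updates"]

    def test_client_update_carries_no_samples(self):
        fields = set(ClientUpdate.__dataclass_fields__)
        assert fields == {"client_id", "round", "n_k", "weights", "metadata"}

    def test_update_metadata_has_no_arrays_beyond_weights(self, feature_clients):
        data, _ = feature_clients
        g = clf_factory().get_flat()
        upd = local_train(data["client-1"], g, clf_factory, "client-1", 0,
                          local_epochs=1)
        assert all(not isinstance(v, np.ndarray) for v in upd.metadata.values())
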