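"""Inner adaptation loop, meta-loss, and meta-optimization of Theta."""

import numpy as np
import pytest

import metaplast as mp
from metaplast.meta import run_inner_loop, meta_loss
from metaplast._dual import Dual
from metaplast.plasticity import NUM_TERMS
from metaplast.tasks import EpisodeTask


def tiny_task(rng, d=4, n_train=3, n_query=4, n_classes=2):
    return EpisodeTask(
        X_train=rng.uniform(0, 1, (n_train, d)),
        y_train=rng.integers(0, n_classes, n_train),
        X_query=rng.uniform(0, 1, (n_query, d)),
        y_query=rng.integers(0, n_classes, n_query),
        class_ids=np.arange(n_classes),
    )


@pytest.fixture
def net_442():
    return mp.NetworkConfig((4, 4, 2), feedback_mode="FA")


class TestInnerLoop:
    def test_zero_rule_leaves_weights_untouched(self, rng, net_442):
        rule = mp.PlasticityCoefficients(np.zeros(NUM_TERMS), (0,))
        task = tiny_task(rng)
        inner = run_inner_loop(rule, task, net_442, seed=3, track_grad=False)
        init = mp.init_network(net_442, seed=3)
        for w0, w1 in zip(init.W, inner.state.W):
            assert np.array_equal(w0, w1)

    def test_zero_rule_accuracy_near_chance(self, rng):
        net = mp.NetworkConfig((8, 6, 4), feedback_mode="FA")
        rule = mp.PlasticityCoefficients(np.zeros(NUM_TERMS), (0,))
        accs = []
        for s in range(10):
            task = tiny_task(np.random.default_rng(s), d=8, n_train=4,
                             n_query=20, n_classes=4)
            inner = run_inner_loop(rule, task, net, seed=s, track_grad=False)
            accs.append(mp.meta_accuracy(inner.state, task.X_query, task.y_query))
        assert abs(np.mean(accs) - 0.25) < 0.15

    def test_episode_stream_length_m_times_k(self):
        spec = mp.SyntheticTaskSpec(input_dim=64, class_pool_size=20, n_per_class=60)
        source = mp.make_synthetic_source(spec, seed=0)
        task = mp.sample_episode(source, M=5, K=50, Q=10, seed=0)
        assert len(task.y_train) == 250        # one weight update per sample
        assert len(task.y_query) == 50

    def test_matches_manual_replay_of_plain_updates(self, rng):
        """The differentiable loop agrees with hand-applied plain-numpy updates."""
        net = mp.NetworkConfig((4, 3, 2), feedback_mode="FA")
        theta = np.zeros(NUM_TERMS)
        theta[[0, 2, 9]] = [0.01, 0.004, 0.003]
        rule = mp.PlasticityCoefficients(theta, (0, 2, 9))
        task = tiny_task(rng, n_train=3)
        inner = run_inner_loop(rule, task, net, seed=9, track_grad=True)

        state = mp.init_network(net, seed=9)
        for x, label in zip(task.X_train, task.y_train):
            trace = mp.forward(state, x)
            errs = mp.propagate_errors(state, trace, mp.output_error(trace, label))
            deltas = []
            for i in range(net.depth):
                s = mp.LocalSignals(trace.y[i], trace.y[i + 1],
                                    errs.e[i], errs.e[i + 1], state.W[i])
                deltas.append(mp.compose_update(rule, s))
            for i in range(net.depth):
                state.W[i] = state.W[i] + deltas[i]
        for w_manual, w_loop in zip(state.W, inner.state.W):
            assert np.allclose(w_manual, w_loop, atol=1e-12)

    def test_blowup_aborts_with_diagnostic(self, rng, net_442):
        theta = np.zeros(NUM_TERMS)
        theta[0] = 1e300
        rule = mp.PlasticityCoefficients(theta, (0,))
        task = tiny_task(rng, n_train=20)
        inner = run_inner_loop(rule, task, net_442, seed=0, track_grad=False)
        assert inner.aborted


class TestMetaLoss:
    def test_no_penalty_equals_query_cross_entropy(self, rng, net_442):
        rule = mp.named_rule("fa_baseline")
        task = tiny_task(rng)
        inner = run_inner_loop(rule, task, net_442, seed=1, track_grad=False)
        loss = meta_loss(inner, task.X_query, task.y_query, rule, l1_lambda=0.0)
        manual = np.mean([-np.log(mp.forward(inner.state, x).y[-1][y])
                          for x, y in zip(task.X_query, task.y_query)])
        assert abs(loss.val - manual) < 1e-10

    def test_l1_penalty_added_exactly(self, rng, net_442):
        theta = np.zeros(NUM_TERMS)
        theta[[0, 2]] = [1e-3, -2e-3]
        rule = mp.PlasticityCoefficients(theta, (0, 2))
        task = tiny_task(rng)
        inner = run_inner_loop(rule, task, net_442, seed=1, track_grad=False)
        l0 = meta_loss(inner, task.X_query, task.y_query, rule, 0.0).val
        l1 = meta_loss(inner, task.X_query, task.y_query, rule, 0.5).val
        assert abs((l1 - l0) - 0.5 * 3e-3) < 1e-12

    def test_hand_computed_two_point_query(self):
        """Trained-network query loss checked against a manual calculation."""
        cfg = mp.NetworkConfig((2, 2, 2), feedback_mode="FA")
        state = mp.init_network(cfg, seed=0)
        state.W[0][:] = [[1.0, 0.0], [0.0, 1.0]]
        state.W[1][:] = [[2.0, 0.0], [0.0, 2.0]]
        inner = mp.InnerLoopResult(state=state, W_dual=[Dual(w) for w in state.W],
                                   active=(0,))
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 0])
        rule = mp.named_rule("fa_baseline")
        loss = meta_loss(inner, X, y, rule, 0.0).val
        manual = 0.0
        for x, lab in zip(X, y):
            h = np.log1p(np.exp(10 * (state.W[0] @ x))) / 10
            z = state.W[1] @ h
            manual += np.log(np.exp(z).sum()) - z[lab]
        assert abs(loss - manual / 2) < 1e-10

    def test_empty_query_rejected(self, rng, net_442):
        rule = mp.named_rule("fa_baseline")
        task = tiny_task(rng)
        inner = run_inner_loop(rule, task, net_442, seed=1, track_grad=False)
        with pytest.raises(ValueError):
            meta_loss(inner, np.empty((0, 4)), np.empty(0), rule, 0.0)


class TestMetaTrain:
    def test_zero_episodes_is_noop(self, net_442):
        cfg = mp.MetaConfig(network=net_442, rule=mp.named_rule("fa_baseline"),
                            episodes=0)
        assert mp.meta_train(cfg, lambda seed: None) == []

    def test_deterministic_given_seed(self, scaled_sampler):
        net = mp.NetworkConfig((64, 20, 10, 5), feedback_mode="FA")
        cfg = mp.MetaConfig(network=net, rule=mp.named_rule("fa_baseline"),
                            episodes=5, trial_seed=11)
        h1 = mp.meta_train(cfg, scaled_sampler)
        h2 = mp.meta_train(cfg, scaled_sampler)
        assert [r.meta_loss for r in h1] == [r.meta_loss for r in h2]
        assert all(np.array_equal(a.theta, b.theta) for a, b in zip(h1, h2))

    def test_bp_single_coefficient_is_plain_sgd_backprop(self, rng):
        """BP mode with only theta_0 equals SGD with learning rate theta_0."""
        net = mp.NetworkConfig((5, 4, 3), feedback_mode="BP")
        lr = 0.02
        theta = np.zeros(NUM_TERMS)
        theta[0] = lr
        rule = mp.PlasticityCoefficients(theta, (0,))
        task = tiny_task(rng, d=5, n_train=10, n_classes=3)
        inner = run_inner_loop(rule, task, net, seed=4, track_grad=False)

        state = mp.init_network(net, seed=4)    # independent SGD implementation
        beta = net.beta
        for x, label in zip(task.X_train, task.y_train):
            z1 = state.W[0] @ x
            y1 = np.log1p(np.exp(beta * z1)) / beta
            z2 = state.W[1] @ y1
            p = np.exp(z2 - z2.max())
            p /= p.sum()
            e2 = p.copy()
            e2[label] -= 1.0
            e1 = (state.W[1].T @ e2) / (1.0 + np.exp(-beta * z1))
            g1 = np.outer(e1, x)
            g2 = np.outer(e2, y1)
            state.W[0] -= lr * g1
            state.W[1] -= lr * g2
        for w_sgd, w_loop in zip(state.W, inner.state.W):
            assert np.allclose(w_sgd, w_loop, atol=1e-10)

    def test_aborted_episode_skips_theta_update(self, scaled_sampler):
        net = mp.NetworkConfig((64, 20, 10, 5), feedback_mode="FA")
        theta = np.zeros(NUM_TERMS)
        theta[0] = 1e300                          # guaranteed blow-up
        cfg = mp.MetaConfig(network=net,
                            rule=mp.PlasticityCoefficients(theta, (0,)),
                            episodes=2, trial_seed=0)
        hist = mp.meta_train(cfg, scaled_sampler)
        assert all(r.aborted for r in hist)
        assert np.array_equal(hist[0].theta, hist[1].theta)
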