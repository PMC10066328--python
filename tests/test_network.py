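"""Forward pass, teaching signals, and backward error propagation."""

import numpy as np
import pytest

import metaplast as mp
from metaplast.network import activate, activate_prime, input_error_factor

PAPER_LAYERS = (784, 170, 130, 100, 70, 47)


def loss_of_state(state, x, label):
    trace = mp.forward(state, x)
    return -np.log(trace.y[-1][label])


class TestInit:
    def test_paper_architecture_shapes(self):
        cfg = mp.NetworkConfig(PAPER_LAYERS)
        st = mp.init_network(cfg, seed=0)
        assert [w.shape for w in st.W] == [(170, 784), (130, 170), (100, 130),
                                           (70, 100), (47, 70)]
        assert [b.shape for b in st.B] == [(784, 170), (170, 130), (130, 100),
                                           (100, 70), (70, 47)]

    def test_same_seed_bitwise_identical(self):
        cfg = mp.NetworkConfig((6, 5, 4, 3))
        a = mp.init_network(cfg, seed=5)
        b = mp.init_network(cfg, seed=5)
        for wa, wb in zip(a.W + a.B, b.W + b.B):
            assert np.array_equal(wa, wb)

    def test_fa_feedback_independent_of_forward(self):
        """Frobenius correlation of B with W^T is ~0 over many seeds."""
        cfg = mp.NetworkConfig((6, 5, 4), feedback_mode="FA")
        corr = []
        for seed in range(100):
            st = mp.init_network(cfg, seed)
            for w, b in zip(st.W, st.B):
                corr.append((b * w.T).sum()
                            / (np.linalg.norm(b) * np.linalg.norm(w)))
        corr = np.asarray(corr)
        sem = corr.std(ddof=1) / np.sqrt(len(corr))
        assert abs(corr.mean()) < 4 * sem

    def test_bp_feedback_is_live_transpose_view(self):
        st = mp.init_network(mp.NetworkConfig((4, 3, 2), feedback_mode="BP"), 0)
        st.W[0][0, 0] = 123.0
        assert st.feedback(0)[0, 0] == 123.0

    @pytest.mark.parametrize("sizes", [(5,), (5, 3), (5, 0, 3, 2), (5, -1, 3, 2)])
    def test_invalid_layer_sizes_rejected(self, sizes):
        with pytest.raises(ValueError):
            mp.NetworkConfig(sizes)


class TestForward:
    def test_matches_hand_coded_matrix_products(self, rng):
        cfg = mp.NetworkConfig((3, 4, 2), beta=10.0)
        st = mp.init_network(cfg, seed=1)
        x = rng.uniform(0, 1, 3)
        tr = mp.forward(st, x)
        z1 = st.W[0] @ x
        y1 = np.log1p(np.exp(10 * z1)) / 10
        z2 = st.W[1] @ y1
        y2 = np.exp(z2) / np.exp(z2).sum()
        assert np.allclose(tr.z[0], z1, atol=1e-12)
        assert np.allclose(tr.y[1], y1, atol=1e-12)
        assert np.allclose(tr.y[2], y2, atol=1e-12)

    def test_zero_weights_give_softplus_of_zero_and_uniform_output(self):
        cfg = mp.NetworkConfig((4, 3, 5), beta=10.0)
        st = mp.init_network(cfg, seed=0)
        for w in st.W:
            w[:] = 0.0
        tr = mp.forward(st, np.ones(4))
        assert np.allclose(tr.y[1], np.log(2) / 10)
        assert np.allclose(tr.y[-1], 0.2)

    def test_softplus_large_argument_no_overflow(self):
        cfg = mp.NetworkConfig((2, 2, 2), beta=10.0)
        val = activate(np.array([5.0, 500.0]), cfg)
        assert abs(val[0] - (5.0 + np.log1p(np.exp(-50.0)) / 10)) < 1e-12
        assert np.isfinite(val[1]) and abs(val[1] - 500.0) < 1e-12

    def test_softmax_output_normalized(self, small_fa_state, rng):
        tr = mp.forward(small_fa_state, rng.uniform(0, 1, 6))
        assert abs(tr.y[-1].sum() - 1.0) < 1e-12
        assert np.all(tr.y[-1] > 0)

    def test_dimension_mismatch_raises(self, small_fa_state):
        with pytest.raises(ValueError):
            mp.forward(small_fa_state, np.zeros(7))


class TestOutputError:
    def test_perfect_prediction_gives_zero(self):
        tr = mp.ForwardTrace(y0=np.zeros(2), z=[np.zeros(5)],
                             y=[np.zeros(2), np.eye(5)[2]])
        assert np.allclose(mp.output_error(tr, 2), 0.0)

    def test_uniform_output_closed_form(self):
        tr = mp.ForwardTrace(y0=np.zeros(2), z=[np.zeros(5)],
                             y=[np.zeros(2), np.full(5, 0.2)])
        assert np.allclose(mp.output_error(tr, 0), [-0.8, 0.2, 0.2, 0.2, 0.2])

    def test_matches_finite_difference_of_cross_entropy(self, rng):
        z = rng.normal(size=6)
        label = 3
        s = np.exp(z) / np.exp(z).sum()
        tr = mp.ForwardTrace(y0=np.zeros(2), z=[z], y=[np.zeros(2), s])
        e = mp.output_error(tr, label)
        h = 1e-6
        for j in range(6):
            zp, zm = z.copy(), z.copy()
            zp[j] += h
            zm[j] -= h
            ce = lambda zz: np.log(np.exp(zz).sum()) - zz[label]
            assert abs(e[j] - (ce(zp) - ce(zm)) / (2 * h)) < 1e-6

    def test_label_out_of_range(self, small_fa_state, rng):
        tr = mp.forward(small_fa_state, rng.uniform(0, 1, 6))
        with pytest.raises(ValueError):
            mp.output_error(tr, 3)


class TestPropagation:
    def test_bp_errors_equal_loss_gradients(self, rng):
        """In BP mode each e_l is the exact gradient of the loss w.r.t. z_l."""
        cfg = mp.NetworkConfig((6, 5, 4, 3), feedback_mode="BP")
        st = mp.init_network(cfg, seed=3)
        x = rng.uniform(0, 1, 6)
        label = 1
        tr = mp.forward(st, x)
        et = mp.propagate_errors(st, tr, mp.output_error(tr, label))
        h = 1e-6
        for l in range(1, cfg.depth + 1):
            z = tr.z[l - 1]
            for j in range(len(z)):
                fd = (_loss_from_layer(st, tr, l, j, h, label)
                      - _loss_from_layer(st, tr, l, j, -h, label)) / (2 * h)
                assert abs(et.e[l][j] - fd) <= 1e-5 * max(abs(fd), 1e-8)

    def test_zero_output_error_gives_zero_trace(self, small_fa_state, rng):
        tr = mp.forward(small_fa_state, rng.uniform(0, 1, 6))
        et = mp.propagate_errors(small_fa_state, tr, np.zeros(3))
        for e in et.e:
            assert np.allclose(e, 0.0)

    def test_linear_in_output_error(self, small_fa_state, rng):
        tr = mp.forward(small_fa_state, rng.uniform(0, 1, 6))
        e1 = rng.normal(size=3)
        e2 = rng.normal(size=3)
        ta = mp.propagate_errors(small_fa_state, tr, 2.0 * e1 + 3.0 * e2)
        tb1 = mp.propagate_errors(small_fa_state, tr, e1)
        tb2 = mp.propagate_errors(small_fa_state, tr, e2)
        for a, b1, b2 in zip(ta.e, tb1.e, tb2.e):
            assert np.allclose(a, 2.0 * b1 + 3.0 * b2, atol=1e-12)

    def test_fa_and_bp_traces_diverge_below_top(self, rng):
        cfg = mp.NetworkConfig((10, 8, 6, 4), feedback_mode="FA")
        st = mp.init_network(cfg, seed=0)
        tr = mp.forward(st, rng.uniform(0, 1, 10))
        angles = mp.layer_alignment(st, tr, 0)
        assert angles[-1] == 0.0
        assert np.all(angles[1:-1] > 1.0)

    def test_synthetic_input_error_factor_is_activation_derivative(self):
        """1 - exp(-beta softplus(z)) equals the softplus derivative exactly."""
        cfg = mp.NetworkConfig((2, 2, 2), beta=10.0)
        z = np.linspace(-5, 5, 201)
        y = activate(z, cfg)
        assert np.allclose(input_error_factor(y, cfg), activate_prime(z, cfg),
                           atol=1e-10)


def _loss_from_layer(state, trace, l, j, h, label):
    """Recompute the loss treating z_l as an independent input, perturbed at j."""
    cfg = state.config
    L = cfg.depth
    z = trace.z[l - 1].copy()
    z[j] += h
    if l == L:
        return np.log(np.exp(z).sum()) - z[label]
    y = activate(z, cfg)
    for i in range(l, L):
        z = state.W[i] @ y
        y = activate(z, cfg) if i < L - 1 else None
    return np.log(np.exp(z).sum()) - z[label]


class TestSerialization:
    def test_round_trip_exact(self, small_fa_state, tmp_path):
        path = tmp_path / "state.npz"
        small_fa_state.save(path)
        loaded = mp.NetworkState.load(path)
        assert loaded.config == small_fa_state.config
        for a, b in zip(small_fa_state.W + small_fa_state.B, loaded.W + loaded.B):
            assert np.array_equal(a, b)
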