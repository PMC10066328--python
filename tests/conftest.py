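"""Shared fixtures: small networks and the scaled-down benchmark runs.

The scaled benchmark (session-scoped, computed lazily) meta-trains the four
reference conditions — backprop and feedback-alignment baselines, the
Hebbian-error rule, and the Oja rule — on synthetic 5-way tasks with a
5-layer 64-40-30-20-5 network, 50 online samples per episode, 100 episodes,
5 trial seeds.  Several tests compare slices of it.
"""

import numpy as np
import pytest

import metaplast as mp

SCALED_LAYERS = (64, 40, 30, 20, 5)
SCALED_SPEC = dict(input_dim=64, class_pool_size=20, n_per_class=60)
N_SEEDS = 5
EPISODES = 100


@pytest.fixture(scope="session")
def scaled_sampler():
    spec = mp.SyntheticTaskSpec(**SCALED_SPEC)
    source = mp.make_synthetic_source(spec, seed=0)
    return mp.episode_sampler(source, M=5, K=10, Q=10)


@pytest.fixture(scope="session")
def scaled_runs(scaled_sampler):
    """dict: (feedback_mode, rule_name) -> list over seeds of episode histories."""
    runs = {}
    for mode, rule_name in [("BP", "fa_baseline"), ("FA", "fa_baseline"),
                            ("FA", "ehebb"), ("FA", "oja")]:
        histories = []
        for seed in range(N_SEEDS):
            cfg = mp.MetaConfig(
                network=mp.NetworkConfig(SCALED_LAYERS, feedback_mode=mode),
                rule=mp.named_rule(rule_name), episodes=EPISODES,
                meta_learning_rate=1e-3, trial_seed=seed)
            histories.append(mp.meta_train(cfg, scaled_sampler))
        runs[(mode, rule_name)] = histories
    return runs


def accuracy_window(histories, sl):
    """Mean meta-accuracy over an episode slice, per seed."""
    return np.array([np.mean([h.meta_accuracy for h in hist[sl]]) for hist in histories])


def angle_window(histories, sl):
    """(n_seeds, L+1) mean per-layer alignment angles over an episode slice."""
    return np.array([np.nanmean([h.alignment_angles for h in hist[sl]], axis=0)
                     for hist in histories])


def orthonormality_window(histories, sl):
    """(n_seeds, L-1) mean per-hidden-layer E_W over an episode slice."""
    return np.array([np.mean([h.orthonormality for h in hist[sl]], axis=0)
                     for hist in histories])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_fa_state():
    return mp.init_network(mp.NetworkConfig((6, 5, 4, 3), feedback_mode="FA"), seed=7)
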