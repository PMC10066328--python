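"""Multi-trial orchestration, bootstrap confidence intervals, and the
per-layer rule-assignment experiment.

Benchmark protocol: every experiment is repeated over independent trials
(20 by default), each with different initial weights and task draws, and
per-episode curves are summarized by the mean with a 98% percentile-bootstrap
confidence band (500 resamples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .meta import MetaConfig, EpisodeResult, meta_train, derive_seed, TaskSampler
from .network import NetworkConfig
from .plasticity import LayerRuleMap, NUM_TERMS


@dataclass
class TrialSet:
    """Per-trial episode histories for one experiment."""

    histories: List[List[EpisodeResult]]
    seeds: List[int]
    descriptor: str = ""

    @property
    def n_trials(self) -> int:
        return len(self.histories)

    def _matrix(self, attr: str) -> np.ndarray:
        return np.array([[getattr(r, attr) for r in h] for h in self.histories])

    def accuracy_matrix(self) -> np.ndarray:
        """(n_trials, episodes) meta-accuracies."""
        return self._matrix("meta_accuracy")

    def loss_matrix(self) -> np.ndarray:
        return self._matrix("meta_loss")

    def angle_array(self) -> np.ndarray:
        """(n_trials, episodes, L+1) per-layer mean alignment angles."""
        return np.array([[r.alignment_angles for r in h] for h in self.histories])

    def orthonormality_array(self) -> np.ndarray:
        """(n_trials, episodes, L-1) per-hidden-layer mean E_W."""
        return np.array([[r.orthonormality for r in h] for h in self.histories])

    def theta_array(self) -> np.ndarray:
        return np.array([[r.theta for r in h] for h in self.histories])


def run_trials(config: MetaConfig, task_sampler: TaskSampler, n_trials: int = 20,
               base_seed: int = 0, descriptor: str = "") -> TrialSet:
    """Repeat a meta-training run with derived per-trial seeds.

    Trial ``t`` runs with ``trial_seed = derive_seed(base_seed, t)``; a trial
    whose every episode aborts is still recorded (blow-ups are data).
    """
    histories, seeds = [], []
    for t in range(n_trials):
        seed = derive_seed(base_seed, t)
        cfg = MetaConfig(network=config.network, rule=config.rule.copy(),
                         episodes=config.episodes,
                         meta_learning_rate=config.meta_learning_rate,
                         l1_lambda=config.l1_lambda, trial_seed=seed,
                         adam_beta1=config.adam_beta1, adam_beta2=config.adam_beta2,
                         adam_eps=config.adam_eps,
                         record_diagnostics=config.record_diagnostics)
        histories.append(meta_train(cfg, task_sampler))
        seeds.append(seed)
    return TrialSet(histories=histories, seeds=seeds, descriptor=descriptor)


@dataclass
class BootstrapCI:
    mean: float
    lower: float
    upper: float
    level: float

    def __post_init__(self):
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("bootstrap interval does not bracket the mean")


def bootstrap_ci(values, level: float = 0.98, n_boot: int = 500, seed: int = 0) -> BootstrapCI:
    """Percentile bootstrap CI of the mean over trials (98%, 500 resamples)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    m = float(values.mean())
    return BootstrapCI(mean=m, lower=float(min(lo, m)), upper=float(max(hi, m)), level=level)


def results_to_frame(history: List[EpisodeResult]) -> pd.DataFrame:
    """Tidy per-episode table (meta_loss, meta_accuracy, theta_r, alpha_l, EW_l)."""
    rows = []
    for r in history:
        row = {"episode": r.episode, "meta_loss": r.meta_loss,
               "meta_accuracy": r.meta_accuracy, "aborted": r.aborted}
        for j in range(NUM_TERMS):
            row[f"theta_{j}"] = r.theta[j]
        if r.alignment_angles is not None:
            for l, a in enumerate(r.alignment_angles):
                row[f"alpha_{l}"] = a
        if r.orthonormality is not None:
            for l, e in enumerate(r.orthonormality, start=1):
                row[f"EW_{l}"] = e
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(trials: TrialSet, level: float = 0.98, n_boot: int = 500,
              seed: int = 0) -> pd.DataFrame:
    """Per-episode mean and bootstrap band of accuracy and loss across trials."""
    acc = trials.accuracy_matrix()
    loss = trials.loss_matrix()
    rows = []
    for ep in range(acc.shape[1]):
        ca = bootstrap_ci(acc[:, ep], level, n_boot, derive_seed(seed, ep, 0))
        cl = bootstrap_ci(loss[:, ep], level, n_boot, derive_seed(seed, ep, 1))
        rows.append({"episode": ep,
                     "accuracy_mean": ca.mean, "accuracy_lo": ca.lower, "accuracy_hi": ca.upper,
                     "loss_mean": cl.mean, "loss_lo": cl.lower, "loss_hi": cl.upper})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-layer rule assignment (which layers get the Hebbian error term)
# ---------------------------------------------------------------------------

#: Rule name -> active term subset for one layer.
ASSIGNMENT_RULES = {"fa": (0,), "ehebb": (0, 2)}

#: The seven canonical assignments for a 3-weight-layer network: every
#: fa/ehebb combination except the Hebbian error term on the first layer
#: alone (its pre-synaptic error is the synthetic input error, so that row
#: is excluded from the protocol).
CANONICAL_ASSIGNMENTS_3LAYER = (
    ("fa", "fa", "fa"),
    ("fa", "ehebb", "fa"),
    ("fa", "fa", "ehebb"),
    ("ehebb", "ehebb", "fa"),
    ("fa", "ehebb", "ehebb"),
    ("ehebb", "fa", "ehebb"),
    ("ehebb", "ehebb", "ehebb"),
)


def assignment_rule_map(assignment) -> LayerRuleMap:
    """Build a shared-coefficient rule restricted per layer by name."""
    theta = np.zeros(NUM_TERMS)
    theta[0] = 1e-3
    per_layer = []
    for name in assignment:
        if name not in ASSIGNMENT_RULES:
            raise ValueError(f"unknown per-layer rule {name!r}")
        per_layer.append(ASSIGNMENT_RULES[name])
    return LayerRuleMap(theta=theta, active_per_layer=tuple(per_layer))


def layer_assignment_experiment(assignments, episodes: int, burn_in: int,
                                task_sampler: TaskSampler,
                                network: NetworkConfig = None,
                                meta_learning_rate: float = 1e-3,
                                base_seed: int = 0,
                                n_trials: int = 1) -> pd.DataFrame:
    """Mean post-burn-in alignment angles for each per-layer rule assignment.

    Meta-learns the shared coefficients (no L1 penalty) for each assignment
    on a 3-hidden-signal network and reports the alignment angles
    ``alpha_0 .. alpha_{L-1}`` averaged over episodes after the burn-in.
    """
    if network is None:
        network = NetworkConfig(layer_sizes=(784, 130, 70, 47), feedback_mode="FA")
    if not 0 <= burn_in < episodes:
        raise ValueError("burn_in must leave a nonempty averaging window")
    L = network.depth
    rows = []
    for a_idx, assignment in enumerate(assignments):
        if len(assignment) != L:
            raise ValueError(f"assignment {assignment} has {len(assignment)} entries, "
                             f"network has {L} weight layers")
        cfg = MetaConfig(network=network, rule=assignment_rule_map(assignment),
                         episodes=episodes, meta_learning_rate=meta_learning_rate,
                         l1_lambda=0.0, record_diagnostics=True)
        trials = run_trials(cfg, task_sampler, n_trials=n_trials,
                            base_seed=derive_seed(base_seed, a_idx))
        angles = trials.angle_array()[:, burn_in:, :L]      # drop the exact-zero top layer
        mean_angles = np.nanmean(angles, axis=(0, 1))
        row = {"assignment": "/".join(assignment)}
        row.update({f"alpha_{l}": mean_angles[l] for l in range(L)})
        rows.append(row)
    return pd.DataFrame(rows)
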