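"""The two-level learning scheme: online adaptation and meta-optimization.

Each *episode* draws a fresh M-way task, re-initializes the network weights
(they are never meta-learned), trains the network online — one forward pass,
one error propagation and one composed plasticity update per sample, single
epoch, batch size one — and then scores the resulting network on the task's
held-out query set.  The meta-loss is that query cross-entropy plus an L1
penalty on the plasticity coefficients; one ADAM step on Theta per episode
descends its exact gradient, obtained by differentiating through the entire
unrolled adaptation loop (forward-mode, see :mod:`metaplast._dual`; the
hidden nonlinearity is differentiated twice in the process, which is why a
smooth activation is required).

Within an episode the diagnostics (alignment angles, orthonormality error)
are computed per training sample and averaged, so every
:class:`EpisodeResult` carries the rule's current teaching-signal quality
alongside its task performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Union

import numpy as np

from . import _dual as d
from .network import (NetworkConfig, NetworkState, init_network, forward,
                      input_error_factor)
from .plasticity import PlasticityCoefficients, LayerRuleMap
from .diagnostics import alignment_angle, orthonormality_from_arrays
from .tasks import EpisodeTask

Rule = Union[PlasticityCoefficients, LayerRuleMap]


def derive_seed(*keys: int) -> int:
    """Deterministic child seed from integer keys (documented counter scheme)."""
    return int(np.random.SeedSequence(tuple(int(k) for k in keys)).generate_state(1)[0] % (2 ** 31))


@dataclass
class MetaConfig:
    """Everything needed to reproduce one meta-training run."""

    network: NetworkConfig
    rule: Rule
    episodes: int
    meta_learning_rate: float = 1e-3          # ADAM step size for Theta
    l1_lambda: float = 0.0                    # zero for single-coefficient runs
    trial_seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    record_diagnostics: bool = True

    def __post_init__(self):
        if self.episodes < 0:
            raise ValueError("episodes must be nonnegative")
        if self.meta_learning_rate <= 0:
            raise ValueError("meta_learning_rate must be positive")
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be nonnegative")


@dataclass
class EpisodeResult:
    """Outcome of one episode (theta is the vector *used* in the episode)."""

    episode: int
    meta_loss: float
    meta_accuracy: float
    theta: np.ndarray
    alignment_angles: np.ndarray      # mean angle per layer, index 0..L
    orthonormality: np.ndarray        # mean E_W per hidden layer, index 1..L-1
    aborted: bool = False


@dataclass
class InnerLoopResult:
    """Trained weights with their sensitivities to the meta-parameters."""

    state: NetworkState
    W_dual: list
    active: tuple
    aborted: bool = False
    alignment_angles: np.ndarray = None
    orthonormality: np.ndarray = None


def _per_layer_active(rule: Rule, n_layers: int) -> list:
    if isinstance(rule, LayerRuleMap):
        if len(rule.active_per_layer) != n_layers:
            raise ValueError(f"rule assigns {len(rule.active_per_layer)} layers, network has {n_layers}")
        return list(rule.active_per_layer)
    return [rule.active] * n_layers


def _theta_duals(rule: Rule, track_grad: bool) -> dict:
    """Meta-parameters as scalar Duals carrying the identity tangent basis."""
    active = rule.active
    P = len(active)
    out = {}
    for j, r in enumerate(active):
        tan = None
        if track_grad:
            tan = np.zeros(P)
            tan[j] = 1.0
        out[r] = d.Dual(rule.theta[r], tan)
    return out


def _term_dual(r, s_y_pre, s_y_post, s_e_pre, s_e_post, s_W):
    """Dual-number mirror of :func:`metaplast.plasticity.term`."""
    if r == 0:
        return d.neg(d.outer(s_e_post, s_y_pre))
    if r == 1:
        return d.neg(d.outer(s_y_post, s_e_pre))
    if r == 2:
        return d.neg(d.outer(s_e_post, s_e_pre))
    if r == 3:
        return d.neg(s_W)
    if r == 4:
        return d.neg(d.outer(d.Dual(np.ones_like(s_y_post.val)), s_e_pre))
    if r == 5:
        return d.neg(d.smul(d.ssum(s_y_post), d.outer(s_e_post, s_y_pre)))
    if r == 6:
        c = d.dot(s_y_post, d.matvec(s_W, s_e_pre))
        return d.neg(d.smul(c, d.outer(s_y_post, s_e_pre)))
    if r == 7:
        c = d.dot(s_y_post, d.matvec(s_W, s_e_pre))
        return d.neg(d.smul(c, d.outer(s_e_post, s_y_pre)))
    if r == 8:
        c = d.dot(s_e_post, d.matvec(s_W, s_y_pre))
        return d.neg(d.smul(c, d.outer(s_y_post, s_e_pre)))
    if r == 9:
        hebb = d.outer(s_y_post, s_y_pre)
        decay = d.outer(s_y_post, d.vecmat(s_y_post, s_W))
        return d.sub(hebb, decay)
    raise ValueError(f"unknown term index {r}")


def _forward_dual(Wd: list, x: np.ndarray, config: NetworkConfig):
    """Dual forward pass; returns (z duals, y duals incl. softmax output)."""
    L = config.depth
    zs = []
    ys = [d.Dual(x)]
    for i in range(L):
        z = d.matvec(Wd[i], ys[i])
        zs.append(z)
        if i == L - 1:
            ys.append(d.softmax(z))
        elif config.activation == "identity":
            ys.append(z)
        else:
            ys.append(d.softplus(z, config.beta))
    return zs, ys


def _sigma_prime_dual(z, config: NetworkConfig):
    if config.activation == "identity":
        return d.Dual(np.ones_like(z.val))
    return d.softplus_prime(z, config.beta)


def run_inner_loop(rule: Rule, task: EpisodeTask, net_config: NetworkConfig,
                   seed: int, track_grad: bool = True,
                   record_diagnostics: bool = False) -> InnerLoopResult:
    """Online single-epoch adaptation of freshly initialized weights.

    Processes ``task.train`` in order, one sample at a time.  When
    ``track_grad`` is set, the returned weights carry exact sensitivities to
    every active plasticity coefficient, accumulated through all update
    steps.  A non-finite weight aborts the episode (blow-up signal).
    """
    state = init_network(net_config, seed)
    L = net_config.depth
    Wd = [d.Dual(w) for w in state.W]
    B_const = None
    if net_config.feedback_mode == "FA":
        B_const = [d.Dual(b) for b in state._B]
    theta_d = _theta_duals(rule, track_grad)
    active_layers = _per_layer_active(rule, L)

    angle_sum = np.zeros(L + 1)
    angle_cnt = np.zeros(L + 1)
    ew_sum = np.zeros(max(L - 1, 0))
    n_seen = 0
    aborted = False

    # Overflow inside a diverging episode is expected and handled by the
    # abort check below; silence the transient numpy warnings it raises.
    with np.errstate(over="ignore", invalid="ignore"):
        aborted, n_seen = _inner_steps(task, net_config, Wd, B_const, theta_d,
                                       active_layers, record_diagnostics,
                                       angle_sum, angle_cnt, ew_sum)
    trained = NetworkState(net_config, [w.val for w in Wd],
                           None if B_const is None else [b.val for b in B_const])
    res = InnerLoopResult(state=trained, W_dual=Wd, active=rule.active, aborted=aborted)
    if record_diagnostics and n_seen > 0:
        with np.errstate(invalid="ignore"):
            res.alignment_angles = np.where(angle_cnt > 0, angle_sum / np.maximum(angle_cnt, 1),
                                            np.nan)
        res.orthonormality = ew_sum / n_seen
    return res


def _inner_steps(task, net_config, Wd, B_const, theta_d, active_layers,
                 record_diagnostics, angle_sum, angle_cnt, ew_sum):
    """One online pass over the train stream; returns (aborted, samples seen)."""
    L = net_config.depth
    n_seen = 0
    for x, label in zip(task.X_train, task.y_train):
        zs, ys = _forward_dual(Wd, x, net_config)
        onehot = np.zeros(net_config.layer_sizes[-1])
        onehot[int(label)] = 1.0
        e = [None] * (L + 1)
        e[L] = d.sub(ys[-1], d.Dual(onehot))
        for i in range(L - 1, 0, -1):
            Bi = d.transpose(Wd[i]) if B_const is None else B_const[i]
            e[i] = d.mul(d.matvec(Bi, e[i + 1]), _sigma_prime_dual(zs[i - 1], net_config))
        B0 = d.transpose(Wd[0]) if B_const is None else B_const[0]
        e[0] = d.mul(d.matvec(B0, e[1]),
                     d.Dual(input_error_factor(np.asarray(x, dtype=float), net_config)))

        if record_diagnostics:
            _accumulate_diagnostics(net_config, Wd, B_const, zs, ys, e,
                                    angle_sum, angle_cnt, ew_sum)

        deltas = []
        for i in range(L):
            delta = None
            for r in active_layers[i]:
                contrib = d.smul(theta_d[r],
                                 _term_dual(r, ys[i], ys[i + 1], e[i], e[i + 1], Wd[i]))
                delta = contrib if delta is None else d.add(delta, contrib)
            deltas.append(delta)
        for i in range(L):
            if deltas[i] is not None:
                Wd[i] = d.add(Wd[i], deltas[i])
        n_seen += 1
        if any(not np.all(np.isfinite(w.val)) for w in Wd):
            return True, n_seen
    return False, n_seen


def _accumulate_diagnostics(config, Wd, B_const, zs, ys, e, angle_sum, angle_cnt, ew_sum):
    """Per-sample alignment angles (vs backprop) and orthonormality errors."""
    L = config.depth
    e_vals = [ei.val for ei in e]
    if B_const is None:                     # BP mode: pathways coincide
        angles = np.zeros(L + 1)
        valid = np.ones(L + 1, dtype=bool)
    else:
        from scipy.special import expit
        e_bp = [None] * (L + 1)
        e_bp[L] = e_vals[L]
        for i in range(L - 1, 0, -1):
            sp = (np.ones_like(zs[i - 1].val) if config.activation == "identity"
                  else expit(config.beta * zs[i - 1].val))
            e_bp[i] = (Wd[i].val.T @ e_bp[i + 1]) * sp
        e_bp[0] = (Wd[0].val.T @ e_bp[1]) * input_error_factor(ys[0].val, config)
        angles = np.empty(L + 1)
        angles[L] = 0.0
        for l in range(L):
            angles[l] = alignment_angle(e_vals[l], e_bp[l])
        valid = ~np.isnan(angles)
    angle_sum[valid] += angles[valid]
    angle_cnt[valid] += 1
    for l in range(1, L):
        ew_sum[l - 1] += orthonormality_from_arrays(Wd[l - 1].val, zs[l - 1].val, ys[l].val)


def meta_loss(result: InnerLoopResult, X_query: np.ndarray, y_query: np.ndarray,
              rule: Rule, l1_lambda: float) -> d.Dual:
    """Mean query cross-entropy plus ``lambda * ||Theta||_1``, as a Dual.

    The L1 subgradient at exactly zero is taken as zero (the convention of
    gradient-based deep-learning frameworks).
    """
    if len(X_query) == 0:
        raise ValueError("empty query set")
    cfg = result.state.config
    total = None
    for x, label in zip(X_query, y_query):
        zs, _ = _forward_dual(result.W_dual, x, cfg)
        ce = d.cross_entropy_logits(zs[-1], int(label))
        total = ce if total is None else d.add(total, ce)
    loss = d.scale(1.0 / len(X_query), total)
    if l1_lambda > 0:
        active = result.active
        pen_val = l1_lambda * np.abs(rule.theta[list(active)]).sum()
        pen_tan = None
        if loss.tan is not None:
            pen_tan = l1_lambda * np.sign(rule.theta[list(active)])
        loss = d.add(loss, d.Dual(pen_val, pen_tan))
    return loss


def meta_accuracy(state: NetworkState, X_query, y_query) -> float:
    """Fraction of query samples whose softmax argmax matches the label."""
    hits = 0
    for x, label in zip(X_query, y_query):
        trace = forward(state, x)
        hits += int(np.argmax(trace.y[-1]) == int(label))
    return hits / len(X_query)


TaskSampler = Callable[[int], EpisodeTask]


def meta_train(config: MetaConfig, task_sampler: TaskSampler) -> List[EpisodeResult]:
    """Run Alg.-style meta-optimization: one task, one ADAM step per episode.

    ``task_sampler(seed)`` must return a fresh :class:`EpisodeTask`.  Fully
    reproducible from ``config.trial_seed``: episode ``eps`` uses derived
    seeds ``derive_seed(trial_seed, eps, 0)`` for the network initialization
    and ``derive_seed(trial_seed, eps, 1)`` for the task draw.  An aborted
    (blown-up) episode is recorded and its Theta update skipped.
    """
    rule = config.rule.copy()
    active = list(rule.active)
    P = len(active)
    m = np.zeros(P)
    v = np.zeros(P)
    t = 0
    history: List[EpisodeResult] = []
    for ep in range(config.episodes):
        task = task_sampler(derive_seed(config.trial_seed, ep, 1))
        net_seed = derive_seed(config.trial_seed, ep, 0)
        inner = run_inner_loop(rule, task, config.network, net_seed,
                               track_grad=True,
                               record_diagnostics=config.record_diagnostics)
        theta_used = rule.theta.copy()
        if inner.aborted:
            history.append(EpisodeResult(ep, float("nan"), float("nan"), theta_used,
                                         inner.alignment_angles, inner.orthonormality,
                                         aborted=True))
            continue
        loss = meta_loss(inner, task.X_query, task.y_query, rule, config.l1_lambda)
        acc = meta_accuracy(inner.state, task.X_query, task.y_query)
        history.append(EpisodeResult(ep, float(loss.val), acc, theta_used,
                                     inner.alignment_angles, inner.orthonormality))
        grad = loss.tan
        if grad is None or not np.all(np.isfinite(grad)):
            continue
        t += 1
        m = config.adam_beta1 * m + (1 - config.adam_beta1) * grad
        v = config.adam_beta2 * v + (1 - config.adam_beta2) * grad ** 2
        m_hat = m / (1 - config.adam_beta1 ** t)
        v_hat = v / (1 - config.adam_beta2 ** t)
        rule.theta[active] -= config.meta_learning_rate * m_hat / (np.sqrt(v_hat) + config.adam_eps)
    return history
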