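"""Fully connected classifier networks with symmetric or fixed random feedback.

The forward model is a bias-free multilayer perceptron: ``z_l = W_{l-1,l}
y_{l-1}``, ``y_l = sigma(z_l)`` with a smoothed-ReLU (softplus) hidden
nonlinearity and a softmax output.  Errors are carried backward by a separate
set of feedback matrices ``B``:

* ``feedback_mode="BP"`` — ``B_{l,l-1}`` is read as the transpose of the
  *current* forward weight ``W_{l-1,l}``, which makes the propagated signals
  the exact gradient of the loss with respect to each pre-activation
  (classical backpropagation).
* ``feedback_mode="FA"`` — ``B`` is a fixed random matrix drawn independently
  of ``W`` (random feedback alignment); the propagated signal is then only a
  pseudo-gradient.

Because the update rules studied here may need a *pre-synaptic* error at the
first layer, where no true backward signal exists, a synthetic input-layer
error ``e_0 = B_{1,0} e_1 * (1 - exp(-beta y_0))`` is always attached to the
error trace.  The elementwise factor is exactly the softplus derivative
``sigma'(z_0)`` expressed through the observable ``y_0 = softplus(z_0)``, so
``e_0`` is the natural continuation of the backward recursion one step past
the input.

Indexing convention used throughout the package: for an ``L``-layer network
with sizes ``n_0 .. n_L``, ``W[i]`` maps layer ``i`` to ``i+1`` (shape
``(n_{i+1}, n_i)``) and ``B[i]`` maps errors from layer ``i+1`` back to
``i`` (shape ``(n_i, n_{i+1})``), for ``i = 0 .. L-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax as _softmax


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and feedback-pathway options.

    Parameters
    ----------
    layer_sizes : sequence of int
        ``n_0 .. n_L`` with the input dimension first and the class count
        last; at least two weight layers are required.
    beta : float
        Smoothness of the softplus activation (the paper-scale default is 10).
    feedback_mode : {"FA", "BP"}
        Fixed random feedback or weight-transposed (gradient) feedback.
    activation : {"softplus", "identity"}
        Hidden nonlinearity; ``identity`` builds the linear network used by
        the feedback-correlation diagnostic.
    """

    layer_sizes: tuple
    beta: float = 10.0
    feedback_mode: str = "FA"
    activation: str = "softplus"

    def __post_init__(self):
        object.__setattr__(self, "layer_sizes", tuple(int(n) for n in self.layer_sizes))
        if len(self.layer_sizes) < 3:
            raise ValueError("need at least 2 weight layers (3 entries in layer_sizes)")
        if any(n <= 0 for n in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.feedback_mode not in ("FA", "BP"):
            raise ValueError(f"unknown feedback_mode {self.feedback_mode!r}")
        if self.activation not in ("softplus", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def depth(self) -> int:
        """Number of weight layers L."""
        return len(self.layer_sizes) - 1


class NetworkState:
    """Forward weights ``W`` and feedback matrices ``B`` of one network.

    In BP mode the feedback matrices are a dynamic *view* of the transposed
    forward weights (re-read on every access through :meth:`feedback`), never
    a copy, so backward signals always track the evolving forward weights.
    """

    def __init__(self, config: NetworkConfig, W: list, B: list):
        self.config = config
        self.W = W
        self._B = B
        L = config.depth
        sizes = config.layer_sizes
        if len(W) != L or (B is not None and len(B) != L):
            raise ValueError("wrong number of weight/feedback matrices")
        for i, w in enumerate(W):
            if w.shape != (sizes[i + 1], sizes[i]):
                raise ValueError(f"W[{i}] has shape {w.shape}, expected {(sizes[i+1], sizes[i])}")

    def feedback(self, i: int) -> np.ndarray:
        """Feedback matrix ``B_{i+1,i}`` (transpose of ``W[i]`` in BP mode)."""
        if self.config.feedback_mode == "BP":
            return self.W[i].T
        return self._B[i]

    @property
    def B(self) -> list:
        return [self.feedback(i) for i in range(self.config.depth)]

    def copy(self) -> "NetworkState":
        return NetworkState(self.config, [w.copy() for w in self.W],
                            None if self._B is None else [b.copy() for b in self._B])

    # -- checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"W_{i}": w for i, w in enumerate(self.W)}
        arrays.update({f"B_{i}": self.feedback(i) for i in range(self.config.depth)})
        np.savez(path, layer_sizes=np.array(self.config.layer_sizes),
                 beta=self.config.beta,
                 feedback_mode=self.config.feedback_mode,
                 activation=self.config.activation, **arrays)

    @classmethod
    def load(cls, path) -> "NetworkState":
        with np.load(path, allow_pickle=False) as data:
            config = NetworkConfig(
                layer_sizes=tuple(int(n) for n in data["layer_sizes"]),
                beta=float(data["beta"]),
                feedback_mode=str(data["feedback_mode"]),
                activation=str(data["activation"]),
            )
            L = config.depth
            W = [data[f"W_{i}"].copy() for i in range(L)]
            B = [data[f"B_{i}"].copy() for i in range(L)]
        return cls(config, W, B)


@dataclass
class ForwardTrace:
    """Per-layer pre-activations and activations from one input.

    ``z[i]`` is the pre-activation of layer ``i+1`` and ``y[i]`` the
    activation of layer ``i`` (so ``y[0]`` is the input and ``y[-1]`` the
    softmax output).
    """

    y0: np.ndarray
    z: list = field(default_factory=list)
    y: list = field(default_factory=list)


@dataclass
class ErrorTrace:
    """Modulatory signals ``e_0 .. e_L`` (``e[0]`` is the synthetic error)."""

    e: list


def glorot_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_network(config: NetworkConfig, seed: int) -> NetworkState:
    """Draw fresh forward and feedback weights (Glorot/Xavier uniform).

    ``W`` and ``B`` are drawn independently, so in FA mode the feedback is
    statistically unrelated to the forward path.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    sizes = config.layer_sizes
    L = config.depth
    W = [glorot_uniform(rng, (sizes[i + 1], sizes[i])) for i in range(L)]
    B = [glorot_uniform(rng, (sizes[i], sizes[i + 1])) for i in range(L)]
    return NetworkState(config, W, B)


def activate(z: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Hidden-layer nonlinearity (overflow-safe softplus, or identity)."""
    if config.activation == "identity":
        return z
    return np.logaddexp(0.0, config.beta * z) / config.beta


def activate_prime(z: np.ndarray, config: NetworkConfig) -> np.ndarray:
    if config.activation == "identity":
        return np.ones_like(z)
    return expit(config.beta * z)


def forward(state: NetworkState, x: np.ndarray) -> ForwardTrace:
    """Run one input through the network, recording all layer quantities."""
    config = state.config
    x = np.asarray(x, dtype=float)
    if x.shape != (config.layer_sizes[0],):
        raise ValueError(f"input has shape {x.shape}, expected ({config.layer_sizes[0]},)")
    trace = ForwardTrace(y0=x, z=[], y=[x])
    h = x
    L = config.depth
    for i in range(L):
        z = state.W[i] @ h
        h = _softmax(z) if i == L - 1 else activate(z, config)
        trace.z.append(z)
        trace.y.append(h)
    return trace


def output_error(trace: ForwardTrace, label: int) -> np.ndarray:
    """Top-layer teaching signal ``e_L = dL/dz_L = y_L - onehot(label)``.

    The adaptation loss is the cross-entropy of the softmax output, whose
    gradient with respect to the output pre-activation has this closed form.
    """
    y_out = trace.y[-1]
    label = int(label)
    if not 0 <= label < y_out.shape[0]:
        raise ValueError(f"label {label} out of range for {y_out.shape[0]} classes")
    e = y_out.copy()
    e[label] -= 1.0
    return e


def input_error_factor(y0: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Elementwise factor of the synthetic input-layer error.

    For the softplus activation, ``1 - exp(-beta * softplus(z))`` equals the
    logistic ``sigma'(z)`` exactly, so expressing the factor through the
    observable ``y_0`` continues the backward recursion past the input layer.
    For the identity activation the derivative is 1.
    """
    if config.activation == "identity":
        return np.ones_like(y0)
    return 1.0 - np.exp(-config.beta * y0)


def propagate_errors(state: NetworkState, trace: ForwardTrace, e_L: np.ndarray) -> ErrorTrace:
    """Carry the top-layer error backward through the feedback pathway.

    ``e_{l-1} = B_{l,l-1} e_l * sigma'(z_{l-1})`` for ``l = L .. 2`` plus the
    synthetic ``e_0``.  In BP mode (``B = W^T``) the result is the exact
    gradient of the loss with respect to every pre-activation.
    """
    config = state.config
    L = config.depth
    e = [None] * (L + 1)
    e[L] = np.asarray(e_L, dtype=float)
    for i in range(L - 1, 0, -1):
        e[i] = (state.feedback(i) @ e[i + 1]) * activate_prime(trace.z[i - 1], config)
    e[0] = (state.feedback(0) @ e[1]) * input_error_factor(trace.y0, config)
    return ErrorTrace(e=e)
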