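"""Interpretability instruments for feedback-trained networks.

Three quantities are used to understand *how* a plasticity rule learns:

* the alignment angle ``alpha_l`` between the modulatory signal a rule
  actually propagates through its feedback matrices and the exact gradient
  signal backprop would have produced from the same forward pass;
* the orthonormality error ``E_W``, a reconstruction-style proximity measure
  to the stable fixed point ``W W^T = I`` of Oja's rule;
* a Monte-Carlo check that, in a linear network with fixed random feedback,
  the expected outer product of consecutive errors ``E[e_l e_{l-1}^T]`` is
  proportional to the transposed feedback matrix — the mechanism by which a
  Hebbian error term pushes forward weights toward the feedback transposes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import subspace_angles
from scipy.special import softmax as _softmax

from .network import NetworkState, ForwardTrace, output_error, propagate_errors

#: Vectors with norm below this are treated as directionless and excluded.
ZERO_NORM_TOL = 1e-12


def alignment_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees (NaN if either is ~zero).

    Identical arrays give exactly 0.  Zero-norm inputs return NaN so that
    averaging code can exclude them instead of imputing an arbitrary angle.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < ZERO_NORM_TOL or nv < ZERO_NORM_TOL:
        return float("nan")
    if np.array_equal(u, v):
        return 0.0
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _bp_view(state: NetworkState) -> NetworkState:
    cfg = dataclasses.replace(state.config, feedback_mode="BP")
    return NetworkState(cfg, state.W, None)


def layer_alignment(state: NetworkState, trace: ForwardTrace, label: int) -> np.ndarray:
    """Per-layer angles between the state's error pathway and backprop's.

    Both error traces start from the same top-layer teaching signal
    ``e_L = dL/dz_L``, so the returned array (indexed ``l = 0 .. L``) is
    exactly 0 at the output and measures only the divergence introduced by
    the feedback matrices below it.  Index 0 is the synthetic input error.
    """
    L = state.config.depth
    e_L = output_error(trace, label)
    e_own = propagate_errors(state, trace, e_L).e
    angles = np.empty(L + 1)
    angles[L] = 0.0
    if state.config.feedback_mode == "BP":
        angles[:L] = 0.0
        return angles
    e_bp = propagate_errors(_bp_view(state), trace, e_L).e
    for l in range(L):
        angles[l] = alignment_angle(e_own[l], e_bp[l])
    return angles


def orthonormality_from_arrays(W: np.ndarray, z: np.ndarray, y_act: np.ndarray) -> float:
    """``E_W = || z - W (W^T y_act) ||^2`` with ``y_act = sigma(z)``."""
    ybar = W.T @ y_act
    r = z - W @ ybar
    return float(r @ r)


def orthonormality_error(state: NetworkState, trace: ForwardTrace, layer: int) -> float:
    """Proximity of ``W[layer-1]`` to an Oja fixed point, from one trace.

    ``layer`` indexes hidden layers ``1 .. L-1``; the softmax output layer is
    excluded (its activation is not the elementwise nonlinearity the measure
    assumes).
    """
    L = state.config.depth
    if not 1 <= layer <= L - 1:
        raise ValueError(f"layer must be a hidden layer in 1..{L - 1}")
    return orthonormality_from_arrays(state.W[layer - 1], trace.z[layer - 1], trace.y[layer])


def principal_subspace_angle(W: np.ndarray, basis: np.ndarray) -> float:
    """Largest principal angle (degrees) between row(W) and span(basis columns)."""
    return float(np.degrees(subspace_angles(W.T, basis).max()))


def feedback_error_correlation(state: NetworkState, n_samples: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of how ``E[e_l e_{l-1}^T]`` aligns with ``B^T``.

    Draws standard-normal inputs and uniform labels, runs the (identity-
    activation) network forward, propagates the cross-entropy teaching signal
    through the fixed feedback pathway, and returns the cosine similarity
    between the flattened sample mean of ``e_l e_{l-1}^T`` and the flattened
    ``B_{l,l-1}^T`` for each hidden layer ``l = 1 .. L-1``.

    In this linear setting ``e_{l-1} = B_{l,l-1} e_l``, so the expectation is
    ``E[e_l e_l^T] B^T``; with near-isotropic error covariance that is nearly
    proportional to ``B^T``, which is why a Hebbian error term drives the
    forward weights toward the feedback transposes.  The statement is
    specific to linear networks and is not asserted for nonlinear ones.
    """
    cfg = state.config
    if cfg.activation != "identity":
        raise ValueError("feedback correlation check requires an identity-activation network")
    rng = np.random.default_rng(seed)
    L = cfg.depth
    sizes = cfg.layer_sizes
    X = rng.standard_normal((int(n_samples), sizes[0]))
    labels = rng.integers(0, sizes[-1], size=int(n_samples))

    H = X
    for i in range(L):
        H = H @ state.W[i].T
    P = _softmax(H, axis=1)
    E = P
    E[np.arange(len(labels)), labels] -= 1.0     # e_L rows
    errors = [None] * (L + 1)
    errors[L] = E
    for l in range(L - 1, -1, -1):               # identity sigma' == 1
        errors[l] = errors[l + 1] @ state.feedback(l).T

    cosines = np.empty(L - 1)
    for l in range(1, L):
        M = errors[l].T @ errors[l - 1] / len(labels)
        target = state.feedback(l - 1).T
        cosines[l - 1] = (M.ravel() @ target.ravel()
                          / (np.linalg.norm(M) * np.linalg.norm(target)))
    return cosines


def oja_train_linear(W0: np.ndarray, X: np.ndarray, lr: float) -> np.ndarray:
    """Train a single linear compression layer with the pure Oja term.

    One online pass over the rows of ``X``:
    ``W <- W + lr * (y x^T - (y y^T) W)`` with ``y = W x``.  Used to verify
    that the Oja pool term performs principal-subspace extraction.
    """
    W = W0.copy()
    for x in X:
        y = W @ x
        W += lr * (np.outer(y, x) - np.outer(y, y) @ W)
    return W
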