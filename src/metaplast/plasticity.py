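"""The candidate plasticity-term pool and parameterized update rules.

A plasticity rule is a linear combination ``F(Theta) = sum_r theta_r F^r`` of
ten candidate terms, each built only from signals locally available to a
synapse: the pre/post-synaptic activations ``y``, the pre/post-synaptic
modulatory errors ``e``, and the current weight matrix ``W``.  The update is
applied additively, ``W <- W + F(Theta)``.

The ten terms (for the weight ``W`` mapping layer l-1 to l):

====  =========================================================  ==========================
 r    formula                                                    interpretation
====  =========================================================  ==========================
 0    ``-e_l y_{l-1}^T``                                         (pseudo-)gradient step
 1    ``-y_l e_{l-1}^T``                                         reversed error/activity
 2    ``-e_l e_{l-1}^T``                                         Hebbian error product
 3    ``-W``                                                     weight decay
 4    ``-1 e_{l-1}^T``                                           pre-synaptic error bias
 5    ``-e_l (1^T y_l) y_{l-1}^T``                               gradient scaled by total
                                                                 post activity
 6    ``-(y_l^T W e_{l-1}) y_l e_{l-1}^T``                       higher-order error term
 7    ``-(y_l^T W e_{l-1}) e_l y_{l-1}^T``                       higher-order gradient term
 8    ``-(e_l^T W y_{l-1}) y_l e_{l-1}^T``                       higher-order error term
 9    ``y_l y_{l-1}^T - (y_l y_l^T) W``                          Oja's subspace rule
====  =========================================================  ==========================

Pure Hebbian plasticity (``y_l y_{l-1}^T``) is deliberately not in the pool —
without a stabilizer it blows activations up — and is represented instead by
its stabilized form, Oja's rule (term 9).  With post-nonlinearity activations
term 9 is the nonlinear variant of Oja's principal-subspace learning rule.

Coefficients are shared across layers ("meta-parameter sharing"), which keeps
the discovered rule global and interpretable; :class:`LayerRuleMap` supports
the ablation where different layers are restricted to different term subsets
while still sharing one coefficient vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NUM_TERMS = 10

#: Named composite rules -> active term subsets.
NAMED_RULES = {
    "fa_baseline": (0,),        # single learned learning-rate (pseudo-gradient only)
    "ehebb": (0, 2),            # + Hebbian error term
    "oja": (0, 9),              # + Oja's rule
    "bio": (0, 2, 9),           # the three-term rule the L1-regularized search selects
    "pool": tuple(range(NUM_TERMS)),
}


@dataclass
class PlasticityCoefficients:
    """Coefficient vector ``Theta`` with an explicit set of active terms.

    Inactive coefficients are pinned to exactly zero; only active ones are
    meta-learned.
    """

    theta: np.ndarray
    active: tuple

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (NUM_TERMS,):
            raise ValueError(f"theta must have {NUM_TERMS} entries")
        self.active = tuple(sorted(int(r) for r in self.active))
        if any(r < 0 or r >= NUM_TERMS for r in self.active):
            raise ValueError("active term indices must be in 0..9")
        if len(set(self.active)) != len(self.active):
            raise ValueError("duplicate active term")
        inactive = np.setdiff1d(np.arange(NUM_TERMS), self.active)
        if np.any(self.theta[inactive] != 0.0):
            raise ValueError("inactive coefficients must be zero")

    def copy(self) -> "PlasticityCoefficients":
        return PlasticityCoefficients(self.theta.copy(), self.active)


@dataclass
class LayerRuleMap:
    """Per-layer restriction of one shared coefficient vector.

    ``active_per_layer[i]`` lists the terms applied to weight matrix ``W[i]``;
    the coefficients themselves remain shared across the network.
    """

    theta: np.ndarray
    active_per_layer: tuple

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (NUM_TERMS,):
            raise ValueError(f"theta must have {NUM_TERMS} entries")
        self.active_per_layer = tuple(tuple(sorted(int(r) for r in layer))
                                      for layer in self.active_per_layer)
        for layer in self.active_per_layer:
            if any(r < 0 or r >= NUM_TERMS for r in layer):
                raise ValueError("active term indices must be in 0..9")

    @property
    def active(self) -> tuple:
        """Union of active terms over layers (the meta-learned coordinates)."""
        out = set()
        for layer in self.active_per_layer:
            out.update(layer)
        return tuple(sorted(out))

    def copy(self) -> "LayerRuleMap":
        return LayerRuleMap(self.theta.copy(), self.active_per_layer)


def named_rule(name: str) -> PlasticityCoefficients:
    """Build a named rule with the standard initialization.

    The pseudo-gradient coefficient ``theta_0`` starts at ``1e-3`` (it plays
    the role of a learning rate); every other coefficient starts at zero and
    is discovered by meta-optimization.
    """
    key = name.lower().replace("-", "_")
    if key not in NAMED_RULES:
        raise ValueError(f"unknown rule {name!r}; choose from {sorted(NAMED_RULES)}")
    active = NAMED_RULES[key]
    theta = np.zeros(NUM_TERMS)
    if 0 in active:
        theta[0] = 1e-3
    return PlasticityCoefficients(theta, active)


@dataclass
class LocalSignals:
    """Signals locally available to one weight matrix during an update."""

    y_pre: np.ndarray
    y_post: np.ndarray
    e_pre: np.ndarray
    e_post: np.ndarray
    W: np.ndarray


def term(r: int, s: LocalSignals) -> np.ndarray:
    """Evaluate candidate plasticity term ``F^r`` on the given local signals."""
    if r == 0:
        return -np.outer(s.e_post, s.y_pre)
    if r == 1:
        return -np.outer(s.y_post, s.e_pre)
    if r == 2:
        return -np.outer(s.e_post, s.e_pre)
    if r == 3:
        return -s.W
    if r == 4:
        return -np.outer(np.ones_like(s.y_post), s.e_pre)
    if r == 5:
        return -s.y_post.sum() * np.outer(s.e_post, s.y_pre)
    if r == 6:
        return -(s.y_post @ s.W @ s.e_pre) * np.outer(s.y_post, s.e_pre)
    if r == 7:
        return -(s.y_post @ s.W @ s.e_pre) * np.outer(s.e_post, s.y_pre)
    if r == 8:
        return -(s.e_post @ s.W @ s.y_pre) * np.outer(s.y_post, s.e_pre)
    if r == 9:
        return np.outer(s.y_post, s.y_pre) - np.outer(s.y_post, s.y_post) @ s.W
    raise ValueError(f"unknown term index {r}")


def compose_update(coeffs: PlasticityCoefficients, s: LocalSignals) -> np.ndarray:
    """Weight increment ``sum_r theta_r F^r(s)`` over the active terms."""
    delta = np.zeros_like(s.W)
    for r in coeffs.active:
        th = coeffs.theta[r]
        if th != 0.0:
            delta += th * term(r, s)
    return delta
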