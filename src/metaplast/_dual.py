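"""Forward-mode (tangent) differentiation over a small meta-parameter vector.

The outer meta-optimization needs the exact gradient of the meta-loss with
respect to the plasticity coefficients Theta, obtained by differentiating
*through* the unrolled online adaptation loop.  Because Theta has at most ten
components, forward-mode accumulation is both exact and cheap: every
intermediate quantity carries a stack of ``P`` directional derivatives
(one per meta-parameter), so memory stays O(network size) regardless of how
many inner-loop steps are unrolled.

A :class:`Dual` wraps a numpy value of shape ``s`` together with a tangent
array of shape ``(P, *s)``; ``tan=None`` encodes an identically-zero tangent
(constants).  Only the handful of operations used by the adaptation loop is
implemented; each one propagates tangents with the standard product/chain
rules.  The result is validated against central finite differences in the
test-suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logsumexp, softmax as _softmax


class Dual:
    """A numpy value with ``P`` directional derivatives (may be ``None`` = 0)."""

    __slots__ = ("val", "tan")

    def __init__(self, val, tan=None):
        self.val = np.asarray(val, dtype=float)
        self.tan = tan

    def __repr__(self):  # pragma: no cover
        p = "0" if self.tan is None else str(self.tan.shape[0])
        return f"Dual(shape={self.val.shape}, P={p})"


def lift(x) -> Dual:
    """Wrap a constant as a zero-tangent Dual (no-op on Duals)."""
    return x if isinstance(x, Dual) else Dual(x)


def _add_tan(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def add(a: Dual, b: Dual) -> Dual:
    return Dual(a.val + b.val, _add_tan(a.tan, b.tan))


def sub(a: Dual, b: Dual) -> Dual:
    bt = None if b.tan is None else -b.tan
    return Dual(a.val - b.val, _add_tan(a.tan, bt))


def neg(a: Dual) -> Dual:
    return Dual(-a.val, None if a.tan is None else -a.tan)


def scale(c: float, a: Dual) -> Dual:
    """Constant scalar times Dual."""
    return Dual(c * a.val, None if a.tan is None else c * a.tan)


def mul(a: Dual, b: Dual) -> Dual:
    """Elementwise product (numpy broadcasting on the value axes)."""
    t = None
    if a.tan is not None:
        t = a.tan * b.val
    if b.tan is not None:
        t = _add_tan(t, a.val * b.tan)
    return Dual(a.val * b.val, t)


def smul(s: Dual, a: Dual) -> Dual:
    """Scalar Dual times array Dual."""
    t = None
    if s.tan is not None:
        t = s.tan.reshape(s.tan.shape[:1] + (1,) * a.val.ndim) * a.val
    if a.tan is not None:
        t = _add_tan(t, s.val * a.tan)
    return Dual(s.val * a.val, t)


def matvec(w: Dual, v: Dual) -> Dual:
    """``W @ v`` for matrix Dual ``W`` (m, k) and vector Dual ``v`` (k,)."""
    t = None
    if w.tan is not None:
        t = w.tan @ v.val                     # (P, m, k) @ (k,) -> (P, m)
    if v.tan is not None:
        t = _add_tan(t, v.tan @ w.val.T)      # (P, k) @ (k, m) -> (P, m)
    return Dual(w.val @ v.val, t)


def vecmat(v: Dual, w: Dual) -> Dual:
    """``W.T @ v`` for matrix Dual ``W`` (m, k) and vector Dual ``v`` (m,)."""
    t = None
    if w.tan is not None:
        # (P, m, k) with (m,): contract the m axis
        t = np.einsum("pmk,m->pk", w.tan, v.val)
    if v.tan is not None:
        t = _add_tan(t, v.tan @ w.val)        # (P, m) @ (m, k) -> (P, k)
    return Dual(w.val.T @ v.val, t)


def transpose(w: Dual) -> Dual:
    return Dual(w.val.T, None if w.tan is None else np.swapaxes(w.tan, 1, 2))


def outer(u: Dual, v: Dual) -> Dual:
    t = None
    if u.tan is not None:
        t = u.tan[:, :, None] * v.val[None, None, :]
    if v.tan is not None:
        t = _add_tan(t, u.val[None, :, None] * v.tan[:, None, :])
    return Dual(np.outer(u.val, v.val), t)


def dot(u: Dual, v: Dual) -> Dual:
    """Inner product of two vector Duals -> scalar Dual with tan shape (P,)."""
    t = None
    if u.tan is not None:
        t = u.tan @ v.val
    if v.tan is not None:
        t = _add_tan(t, v.tan @ u.val)
    return Dual(u.val @ v.val, t)


def ssum(v: Dual) -> Dual:
    return Dual(v.val.sum(), None if v.tan is None else v.tan.sum(axis=1))


def softplus(z: Dual, beta: float) -> Dual:
    """Smoothed ReLU ``log(1 + exp(beta z)) / beta`` (log-sum-exp stable)."""
    val = np.logaddexp(0.0, beta * z.val) / beta
    t = None if z.tan is None else expit(beta * z.val) * z.tan
    return Dual(val, t)


def softplus_prime(z: Dual, beta: float) -> Dual:
    """Derivative of the smoothed ReLU: the logistic ``1/(1+exp(-beta z))``.

    Its own tangent uses the second derivative ``beta s (1 - s)`` — this is
    where the activation is differentiated twice when the meta-gradient flows
    through the error-propagation step.
    """
    s = expit(beta * z.val)
    t = None if z.tan is None else beta * s * (1.0 - s) * z.tan
    return Dual(s, t)


def softmax(z: Dual) -> Dual:
    s = _softmax(z.val)
    if z.tan is None:
        return Dual(s, None)
    t = s * z.tan - s * (z.tan @ s)[:, None]
    return Dual(s, t)


def cross_entropy_logits(z: Dual, label: int) -> Dual:
    """``-log softmax(z)[label]`` as a scalar Dual, computed stably."""
    val = logsumexp(z.val) - z.val[label]
    if z.tan is None:
        return Dual(val, None)
    g = _softmax(z.val)
    g[label] -= 1.0
    return Dual(val, z.tan @ g)
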