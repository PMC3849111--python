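"""Dual numeric backend for frequency-domain formulas.

The analytic Laplace-domain kernels accept either numpy complex arrays
(fast, double precision) or a single mpmath scalar (arbitrary precision).
The latter is what allows the inverse Laplace transform to certify
pointwise relative accuracy deep in the exponential tail of a response,
where double-precision evaluation of the transform itself becomes the
accuracy bottleneck. These helpers dispatch the handful of special
operations; ordinary arithmetic is generic already.
"""

from __future__ import annotations

import numpy as np
import mpmath as mp

__all__ = ["is_mp", "as_omega", "exp", "sqrt", "positive_real_sqrt"]


def is_mp(x) -> bool:
    return isinstance(x, (mp.mpf, mp.mpc))


def as_omega(x):
    """Canonicalise the Laplace variable: mpmath scalars pass through,
    everything else becomes a complex numpy array."""
    if is_mp(x):
        return mp.mpc(x)
    return np.asarray(x, dtype=complex)


def exp(x):
    return mp.exp(x) if is_mp(x) else np.exp(x)


def sqrt(x):
    return mp.sqrt(x) if is_mp(x) else np.sqrt(x)


def positive_real_sqrt(x):
    """Principal square root flipped onto Re >= 0."""
    g = sqrt(x)
    if is_mp(g):
        return -g if g.real < 0 else g
    return np.where(g.real < 0, -g, g)
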