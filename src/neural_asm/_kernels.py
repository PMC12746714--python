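"""Compiled inner loops for iterative value-neuron inference.

The hidden-state settling loop runs ``inference_iters`` explicit-Euler steps
per time step, per trial, per epoch, and dominates the runtime of both
memorisation and monitoring; it is therefore compiled with numba. A plain
numpy twin with identical semantics (`settle_hidden_np`) backs the numerical
oracle tests and any platform where compilation is undesirable.

Activation codes: 0 = linear (identity), 1 = tanh.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ACT_LINEAR = 0
ACT_TANH = 1


@njit(cache=True)
def settle_hidden(a, W_F, W_F_T, x, iters, lr, act_id):  # pragma: no cover - compiled
    """Gradient descent of z on F = ||z - a||^2 + ||x - W_F f(z)||^2.

    ``a`` is the temporal prediction W_H f(z_prev), which is also the
    starting point of the descent. Returns the settled z and the energy at
    every iterate (length ``iters + 1``; entry 0 is the energy at the start,
    the last entry is the converged energy).
    """
    n_h = a.shape[0]
    n_x = x.shape[0]
    z = a.copy()
    energies = np.empty(iters + 1)
    for it in range(iters + 1):
        if act_id == ACT_TANH:
            fz = np.tanh(z)
        else:
            fz = z.copy()
        eps_x = x - W_F @ fz
        e = 0.0
        for i in range(n_h):
            d = z[i] - a[i]
            e += d * d
        for i in range(n_x):
            e += eps_x[i] * eps_x[i]
        energies[it] = e
        if it == iters:
            break
        corr = W_F_T @ eps_x
        if act_id == ACT_TANH:
            for i in range(n_h):
                z[i] += lr * (-(z[i] - a[i]) + (1.0 - fz[i] * fz[i]) * corr[i])
        else:
            for i in range(n_h):
                z[i] += lr * (-(z[i] - a[i]) + corr[i])
    return z, energies


def settle_hidden_np(a, W_F, x, iters, lr, act_id):
    """Reference numpy implementation of :func:`settle_hidden`."""
    z = a.copy()
    energies = np.empty(iters + 1)
    for it in range(iters + 1):
        fz = np.tanh(z) if act_id == ACT_TANH else z
        eps_x = x - W_F @ fz
        eps_z = z - a
        energies[it] = eps_z @ eps_z + eps_x @ eps_x
        if it == iters:
            break
        corr = W_F.T @ eps_x
        fprime = (1.0 - fz**2) if act_id == ACT_TANH else np.ones_like(z)
        z = z + lr * (-eps_z + fprime * corr)
    return z, energies
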