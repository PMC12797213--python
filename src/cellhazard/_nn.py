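"""Minimal MLP + Adam building blocks on top of autograd.

All networks in this package are small fully-connected nets trained on CPU.
Parameters are kept as flat lists of (W, b) numpy arrays so they can be
serialized to .npz checkpoints and hashed for freeze checks.
"""

from __future__ import annotations

import hashlib

import autograd.numpy as anp
import numpy as np


def init_mlp(sizes, rng):
    """Glorot-initialised parameters for a fully connected net.

    sizes: [in, hidden..., out]; returns list of (W, b) pairs.
    """
    params = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (n_in + n_out))
        W = rng.normal(0.0, scale, size=(n_in, n_out))
        b = np.zeros(n_out)
        params.append((W, b))
    return params


def mlp_forward(params, x, activation=anp.tanh):
    """Forward pass; activation on hidden layers, linear final layer."""
    h = x
    for W, b in params[:-1]:
        h = activation(anp.dot(h, W) + b)
    W, b = params[-1]
    return anp.dot(h, W) + b


def softplus(x):
    # numerically stable: log(1 + e^x) = max(x,0) + log1p(e^{-|x|})
    return anp.maximum(x, 0.0) + anp.log1p(anp.exp(-anp.abs(x)))


def flatten_params(tree):
    """Flatten a nested structure of arrays into one vector (for hashing)."""
    out = []

    def rec(node):
        if isinstance(node, (list, tuple)):
            for item in node:
                rec(item)
        else:
            out.append(np.asarray(node).ravel())

    rec(tree)
    return np.concatenate(out) if out else np.zeros(0)


def params_hash(tree) -> str:
    """SHA-256 of the flattened parameter vector (freeze-contract checks)."""
    flat = np.ascontiguousarray(flatten_params(tree), dtype=np.float64)
    return hashlib.sha256(flat.tobytes()).hexdigest()


class Adam:
    """Adam optimiser over an arbitrary nested list/tuple structure of arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = self._zeros_like(params)
        self.v = self._zeros_like(params)

    def _zeros_like(self, node):
        if isinstance(node, (list, tuple)):
            return [self._zeros_like(x) for x in node]
        return np.zeros_like(np.asarray(node, dtype=float))

    def step(self, params, grads):
        self.t += 1
        return self._step(params, grads, self.m, self.v)

    def _step(self, p, g, m, v):
        if isinstance(p, (list, tuple)):
            return [self._step(pi, gi, mi, vi) for pi, gi, mi, vi in zip(p, g, m, v)]
        g = np.asarray(g, dtype=float)
        m[...] = self.beta1 * m + (1 - self.beta1) * g
        v[...] = self.beta2 * v + (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1**self.t)
        vhat = v / (1 - self.beta2**self.t)
        return np.asarray(p) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
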