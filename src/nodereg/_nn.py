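"""Minimal feed-forward network with hand-written reverse mode, plus Adam.

The velocity field of the flow map is a small multilayer perceptron
(input dim d, three tanh hidden layers, linear output of dim d).  The
package trains it with plain reverse-mode accumulation written out
explicitly: the network is tiny and evaluated in large point batches, so
a full autodiff framework buys nothing here.  Training runs in float32
for throughput; parameters can be promoted to float64 on export.
"""

from __future__ import annotations

import numpy as np

__all__ = ["VelocityNetwork", "Adam"]


class VelocityNetwork:
    """MLP velocity field ``NN(x; W, b)`` with matching input/output dim.

    Parameters are a list of ``(W, b)`` pairs, ``W`` of shape
    ``(n_in, n_out)``.  Hidden activations are tanh; the output layer is
    linear.  ``zero_last_layer`` initialisation makes the network vanish
    identically, so the induced flow starts as the exact identity.
    """

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 activation: str = "tanh"):
        if len(params) < 2:
            raise ValueError("network needs at least one hidden layer")
        if activation not in ("tanh", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params = [(np.asarray(W), np.asarray(b)) for W, b in params]
        d_in = self.params[0][0].shape[0]
        d_out = self.params[-1][0].shape[1]
        if d_in != d_out:
            raise ValueError(f"input dim {d_in} != output dim {d_out}")
        for W, b in self.params:
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite network parameters")
        self.dim = d_in

    # -- construction -------------------------------------------------

    @classmethod
    def create(
        cls,
        dim: int,
        hidden: tuple[int, ...] = (40, 40, 40),
        rng: np.random.Generator | None = None,
        init_scale: float = 0.5,
        dtype=np.float32,
    ) -> "VelocityNetwork":
        """Glorot-style small random init with a zeroed output layer."""
        rng = np.random.default_rng() if rng is None else rng
        widths = (dim, *hidden, dim)
        params = []
        for i in range(len(widths) - 1):
            n_in, n_out = widths[i], widths[i + 1]
            if i == len(widths) - 2:
                W = np.zeros((n_in, n_out), dtype=dtype)
            else:
                W = (init_scale * rng.standard_normal((n_in, n_out))
                     / np.sqrt(n_in)).astype(dtype)
            params.append((W, np.zeros(n_out, dtype=dtype)))
        return cls(params)

    @property
    def widths(self) -> tuple[int, ...]:
        return (self.params[0][0].shape[0],
                *(W.shape[1] for W, _ in self.params))

    def astype(self, dtype) -> "VelocityNetwork":
        return VelocityNetwork(
            [(W.astype(dtype), b.astype(dtype)) for W, b in self.params],
            self.activation)

    def copy(self) -> "VelocityNetwork":
        return VelocityNetwork([(W.copy(), b.copy()) for W, b in self.params],
                               self.activation)

    # -- evaluation ---------------------------------------------------

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Evaluate on an ``(N, d)`` batch.

        When ``cache`` is a list it receives the hidden activations
        needed by :meth:`vjp` / :meth:`input_jacobian`.
        """
        a = x
        acts = [a]
        n_layers = len(self.params)
        act = np.tanh if self.activation == "tanh" else (lambda z: z)
        for i, (W, b) in enumerate(self.params):
            z = a @ W + b
            a = z if i == n_layers - 1 else act(z)
            if i < n_layers - 1:
                acts.append(a)
        if cache is not None:
            cache[:] = acts
        return a

    def vjp(self, cache: list, gy: np.ndarray):
        """Backprop ``gy`` (N, d); returns (gx, grads) with grads like params."""
        grads = [None] * len(self.params)
        g = gy
        for i in range(len(self.params) - 1, -1, -1):
            W, _ = self.params[i]
            a_prev = cache[i]
            grads[i] = (a_prev.T @ g, g.sum(axis=0))
            g = g @ W.T
            if i > 0 and self.activation == "tanh":
                g = g * (1.0 - cache[i] ** 2)
        return g, grads

    def input_jacobian(self, cache: list) -> np.ndarray:
        """Exact Jacobian ``A[n, i, j] = dNN_i/dx_j`` from cached activations."""
        W0, _ = self.params[0]

        def dact(a):
            return 1.0 - a ** 2 if self.activation == "tanh" \
                else np.ones_like(a)

        # M[n, j, k] accumulates d(hidden_k)/d(x_j)
        M = W0[None, :, :] * dact(cache[1])[:, None, :]
        for i in range(1, len(self.params) - 1):
            W, _ = self.params[i]
            M = (M @ W) * dact(cache[i + 1])[:, None, :]
        J = M @ self.params[-1][0]            # (N, d_in, d_out)
        return np.swapaxes(J, 1, 2)           # (N, d_out, d_in)

    # -- parameter vector helpers ------------------------------------

    def flat_arrays(self) -> list[np.ndarray]:
        out = []
        for W, b in self.params:
            out.extend([W, b])
        return out


class Adam:
    """Adam over a list of NumPy arrays updated in place."""

    def __init__(self, arrays: list[np.ndarray], lr: float = 5e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            a -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
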