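"""Minimal dense/1D-convolutional neural network layers with manual
backpropagation and an Adam optimizer, in pure numpy.

The focus-correction networks are small (a two-block 1D CNN trunk and a few
fully connected layers), and the training loop needs gradients that flow
from a critic's output back into the actor's action — a bespoke path that
generic fit()-style regressors cannot expose.  The layers here implement
exactly what those networks need: forward caching, reverse-mode gradients
with respect to both parameters and inputs, soft (Polyak) parameter
averaging for target networks, and deterministic seeded initialization.

Conventions: batch-first arrays; convolution inputs are (B, C, L); dense
inputs are (B, F).  ``Sequential.backward`` returns the gradient with
respect to the network input and leaves per-layer parameter gradients in
``layer.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: default parameter/computation dtype; single precision is plenty for the
#: small networks here and roughly halves CPU time
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Dense",
    "Conv1d",
    "MaxPool1d",
    "ReLU",
    "Tanh",
    "Flatten",
    "Sequential",
    "Adam",
    "soft_update",
]


class Layer:
    """Base class; layers without parameters keep empty dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        scale: float | None = None,
        dtype=DTYPE,
    ):
        super().__init__()
        # He-style fan-in scaling unless overridden
        s = scale if scale is not None else np.sqrt(2.0 / n_in)
        self.params = {
            "W": (rng.standard_normal((n_in, n_out)) * s).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Conv1d(Layer):
    """Valid (no-padding) 1D cross-correlation: (B, C_in, L) -> (B, C_out, L-k+1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype=DTYPE):
        super().__init__()
        fan_in = c_in * kernel
        self.kernel = kernel
        self.params = {
            "W": (rng.standard_normal((c_out, c_in, kernel)) * np.sqrt(2.0 / fan_in)).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def forward(self, x):
        k = self.kernel
        B, C, L = x.shape
        Lp = L - k + 1
        cols = sliding_window_view(x, k, axis=2)  # (B, C, L', k) view
        cols2 = cols.transpose(0, 2, 1, 3).reshape(B * Lp, C * k)
        self._cols2 = cols2
        self._shape = (B, C, L)
        W2 = self.params["W"].reshape(-1, C * k)  # (O, C*k)
        out = cols2 @ W2.T + self.params["b"]
        return out.reshape(B, Lp, -1).transpose(0, 2, 1)

    def backward(self, dout):
        k = self.kernel
        B, C, L = self._shape
        O, Lp = dout.shape[1], dout.shape[2]
        dout2 = dout.transpose(0, 2, 1).reshape(B * Lp, O)
        self.grads = {
            "W": (dout2.T @ self._cols2).reshape(O, C, k),
            "b": dout.sum(axis=(0, 2)),
        }
        # full correlation of dout with the flipped kernels recovers dx
        pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        dcols = sliding_window_view(pad, k, axis=2)  # (B, O, L, k)
        dcols2 = dcols.transpose(0, 2, 1, 3).reshape(B * L, O * k)
        # (O*k, C) map of the flipped kernels
        w_map = self.params["W"][:, :, ::-1].transpose(0, 2, 1).reshape(O * k, C)
        return (dcols2 @ w_map).reshape(B, L, C).transpose(0, 2, 1)


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the last axis (trailing remainder
    samples are dropped, as in frameworks' default floor behaviour)."""

    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        k = self.kernel
        B, C, L = x.shape
        Lp = L // k
        self._in_shape = x.shape
        if k == 2:  # fast path: pairwise comparison
            a = x[:, :, 0 : 2 * Lp : 2]
            b = x[:, :, 1 : 2 * Lp : 2]
            self._left = a >= b
            return np.where(self._left, a, b)
        xt = x[:, :, : Lp * k].reshape(B, C, Lp, k)
        self._argmax = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, dout):
        k = self.kernel
        B, C, Lp = dout.shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        if k == 2:
            dx[:, :, 0 : 2 * Lp : 2] = np.where(self._left, dout, 0.0)
            dx[:, :, 1 : 2 * Lp : 2] = np.where(self._left, 0.0, dout)
            return dx
        dxt = np.zeros((B, C, Lp, k), dtype=dout.dtype)
        np.put_along_axis(dxt, self._argmax[..., None], dout[..., None], axis=3)
        dx[:, :, : Lp * k] = dxt.reshape(B, C, Lp * k)
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        """Yield (layer, name, array) triples for all trainable parameters."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name, layer.params[name]

    def state_arrays(self):
        """Flat {index.name: array} view, for checkpointing."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{i}.{name}"] = arr
        return out

    def load_state_arrays(self, state):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(state[f"{i}.{name}"])

    def copy_from(self, other: "Sequential"):
        for layer, o_layer in zip(self.layers, other.layers):
            for name in layer.params:
                layer.params[name] = o_layer.params[name].copy()


class Adam:
    """Adam over one or more Sequential networks' parameters."""

    def __init__(self, nets, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if not isinstance(nets, (list, tuple)):
            nets = [nets]
        self.nets = nets
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for key, layer, name in self._iter_params():
            self.m[key] = np.zeros_like(layer.params[name])
            self.v[key] = np.zeros_like(layer.params[name])

    def _iter_params(self):
        for ni, net in enumerate(self.nets):
            for li, layer in enumerate(net.layers):
                for name in layer.params:
                    yield (ni, li, name), layer, name

    def step(self):
        """Apply one update from the gradients currently stored in the
        layers' ``grads`` dicts."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for key, layer, name in self._iter_params():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
            v = self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            layer.params[name] = layer.params[name] - self.lr * (m / bias1) / (
                np.sqrt(v / bias2) + self.eps
            )


def soft_update(target: Sequential, source: Sequential, tau: float):
    """Polyak averaging: target <- (1 - tau) * target + tau * source."""
    for t_layer, s_layer in zip(target.layers, source.layers):
        for name in t_layer.params:
            t_layer.params[name] = (
                (1.0 - tau) * t_layer.params[name] + tau * s_layer.params[name]
            )
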