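"""Minimal 1-D convolutional network stack in numpy.

Implements exactly the pieces the SpO2 regressors need — channel
combination (pointwise linear mixing across color channels), temporal
convolution, max pooling, batch normalization, dropout, and dense heads —
with hand-written backward passes and an Adam optimizer.  Everything is
seeded through an explicit ``numpy.random.Generator``, so training runs
are bit-reproducible.

Array convention: convolutional layers operate on ``(N, C, L)`` batches
(N segments, C channels, L time samples); dense layers on ``(N, F)``.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Layer",
    "ChannelMix",
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "BatchNorm1d",
    "Dropout",
    "Flatten",
    "Dense",
    "PerChannelStack",
    "Network",
    "Adam",
    "rmse_loss",
]


class Layer:
    """Base layer: forward caches what backward needs; params are (value, grad)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class ChannelMix(Layer):
    """Channel combination layer: V = act(W U + b 1^T).

    ``W`` (Cout x Cin) linearly recombines the input channels pointwise
    along time; ``b`` adds a per-output-channel intercept shared by every
    time sample; the activation is ReLU or identity (the linear ablation).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 activation: str = "relu"):
        if activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.activation = activation

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[1] != self.W.shape[1]:
            raise ValueError(
                f"expected (N, {self.W.shape[1]}, L) input, got {x.shape}"
            )
        self._x = x
        z = np.einsum("oc,ncl->nol", self.W, x) + self.b[None, :, None]
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, gy):
        if self.activation == "relu":
            gy = gy * self._mask
        self.gW[...] = np.einsum("nol,ncl->oc", gy, self._x)
        self.gb[...] = gy.sum(axis=(0, 2))
        return np.einsum("oc,nol->ncl", self.W, gy)

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Conv1d(Layer):
    """Temporal convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.k = kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / (c_in * kernel)), size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def _cols(self, x):
        n, c, L = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        s = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, shape=(n, c, L, self.k), strides=(s[0], s[1], s[2], s[2])
        )
        # (N, L, C*k)
        return view.transpose(0, 2, 1, 3).reshape(n, L, c * self.k)

    def forward(self, x, train=False):
        self._shape = x.shape
        self._cols_cache = self._cols(x)
        wmat = self.W.reshape(self.W.shape[0], -1)  # (Cout, C*k)
        y = self._cols_cache @ wmat.T + self.b  # (N, L, Cout)
        return y.transpose(0, 2, 1)

    def backward(self, gy):
        n, c, L = self._shape
        g = gy.transpose(0, 2, 1)  # (N, L, Cout)
        wmat = self.W.reshape(self.W.shape[0], -1)
        self.gW[...] = np.einsum("nlo,nlf->of", g, self._cols_cache).reshape(self.W.shape)
        self.gb[...] = g.sum(axis=(0, 1))
        dcols = g @ wmat  # (N, L, C*k)
        dcols = dcols.reshape(n, L, c, self.k)
        pl = (self.k - 1) // 2
        dxp = np.zeros((n, c, L + self.k - 1))
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pl : pl + L]

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool1d(Layer):
    """Max pooling along time with the given downsampling factor."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, train=False):
        n, c, L = x.shape
        f = self.factor
        Lc = (L // f) * f
        self._shape = x.shape
        xv = x[:, :, :Lc].reshape(n, c, Lc // f, f)
        self._arg = xv.argmax(axis=3)
        return xv.max(axis=3)

    def backward(self, gy):
        n, c, L = self._shape
        f = self.factor
        Lo = gy.shape[2]
        dx = np.zeros((n, c, Lo, f))
        idx = np.indices((n, c, Lo))
        dx[idx[0], idx[1], idx[2], self._arg] = gy
        out = np.zeros(self._shape)
        out[:, :, : Lo * f] = dx.reshape(n, c, Lo * f)
        return out


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._train = train
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, gy):
        self.ggamma[...] = (gy * self._xhat).sum(axis=(0, 2))
        self.gbeta[...] = gy.sum(axis=(0, 2))
        gxhat = gy * self.gamma[None, :, None]
        if not self._train:
            return gxhat / self._std[None, :, None]
        m = gy.shape[0] * gy.shape[2]
        return (
            gxhat
            - gxhat.mean(axis=(0, 2))[None, :, None]
            - self._xhat * (gxhat * self._xhat).mean(axis=(0, 2))[None, :, None]
        ) / self._std[None, :, None]

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gy):
        self.gW[...] = gy.T @ self._x
        self.gb[...] = gy.sum(axis=0)
        return gy @ self.W

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class PerChannelStack(Layer):
    """Independent sub-networks per input channel, outputs concatenated.

    Used by the feature-extraction-first architecture: each color channel
    gets its own (unshared) temporal feature extractor.
    """

    def __init__(self, stacks: list[list[Layer]]):
        self.stacks = stacks

    def forward(self, x, train=False):
        if x.shape[1] != len(self.stacks):
            raise ValueError(f"expected {len(self.stacks)} channels, got {x.shape[1]}")
        outs = []
        self._n_out = []
        for c, stack in enumerate(self.stacks):
            h = x[:, c : c + 1, :]
            for layer in stack:
                h = layer.forward(h, train=train)
            outs.append(h)
            self._n_out.append(h.shape[1])
        return np.concatenate(outs, axis=1)

    def backward(self, gy):
        grads = []
        ofs = 0
        for c, stack in enumerate(self.stacks):
            g = gy[:, ofs : ofs + self._n_out[c], :]
            ofs += self._n_out[c]
            for layer in reversed(stack):
                g = layer.backward(g)
            grads.append(g)
        return np.concatenate(grads, axis=1)

    def parameters(self):
        return [p for stack in self.stacks for layer in stack for p in layer.parameters()]


class Network:
    """A simple sequential network with scalar regression output."""

    def __init__(self, layers: list[Layer], name: str = "network"):
        self.layers = layers
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h.ravel()

    def backward(self, gy: np.ndarray) -> None:
        g = np.asarray(gy).reshape(-1, 1)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i : i + batch_size], train=False))
        return np.concatenate(out)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for layer in self.layers for p in layer.parameters()]

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v, _ in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [v.copy() for v, _ in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match network parameters")
        for (v, _), s in zip(params, state):
            v[...] = s

    def clone_state(self) -> list[np.ndarray]:
        return copy.deepcopy(self.state_dict())


class Adam:
    """Adam optimizer over a network's (value, grad) parameter pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(v) for v, _ in params]
        self.v = [np.zeros_like(v) for v, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (val, grad) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad**2
            val -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def rmse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Root-mean-squared-error loss and its gradient w.r.t. the predictions."""
    diff = pred - target
    mse = float(np.mean(diff**2))
    rmse = np.sqrt(mse)
    if rmse < 1e-12:
        return rmse, np.zeros_like(diff)
    return rmse, diff / (diff.size * rmse)
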