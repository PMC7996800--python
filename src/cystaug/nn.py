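"""Minimal seeded neural-network engine on numpy (NHWC, float32).

Provides exactly the layers the DCGAN and the CNN classifiers in this package
need — dense, convolution, transposed convolution, batch normalization,
LeakyReLU/ReLU/sigmoid, dropout, max-pooling — with hand-written backward
passes, plus the five adaptive optimizers used in the hyperparameter grid.
Everything is single-threaded numpy, so identical seeds give identical
training trajectories.

Conventions: images are (N, H, W, C); convolutions use TensorFlow-style
"same"/"valid" padding; a transposed convolution with "same" padding maps
(N, H, W, Cin) to (N, H·S, W·S, Cout) exactly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "MaxPool2D",
    "Flatten",
    "Reshape",
    "Sequential",
    "make_optimizer",
    "softmax",
    "softmax_cross_entropy",
]

F32 = np.float32


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base layer: optional params/grads dicts and a cached forward state."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": _glorot(rng, (n_in, n_out), n_in, n_out),
            "b": np.zeros(n_out, dtype=F32),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


def _same_pads(L: int, F: int, S: int) -> tuple[int, int]:
    """TensorFlow 'same' padding for output size ceil(L/S)."""
    out = -(-L // S)
    total = max((out - 1) * S + F - L, 0)
    return total // 2, total - total // 2


def _im2col(xp: np.ndarray, F: int, S: int, ho: int, wo: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N, ho, wo, F, F, C) window view with stride S."""
    win = sliding_window_view(xp, (F, F), axis=(1, 2))  # (N, Hp-F+1, Wp-F+1, C, F, F)
    win = win[:, : (ho - 1) * S + 1 : S, : (wo - 1) * S + 1 : S]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


def _col_scatter(dcols: np.ndarray, shape, F: int, S: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add windows back onto the image."""
    out = np.zeros(shape, dtype=dcols.dtype)
    n, ho, wo = dcols.shape[:3]
    for i in range(F):
        for j in range(F):
            out[:, i : i + (ho - 1) * S + 1 : S, j : j + (wo - 1) * S + 1 : S, :] += dcols[
                :, :, :, i, j, :
            ]
    return out


class Conv2D(Layer):
    """2-D convolution, kernel F×F, stride S, 'same' or 'valid'+explicit pad."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        F: int,
        S: int,
        padding,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.F, self.S, self.padding = F, S, padding
        self.c_in, self.c_out = c_in, c_out
        fan_in, fan_out = F * F * c_in, F * F * c_out
        self.params = {
            "W": _glorot(rng, (F, F, c_in, c_out), fan_in, fan_out),
            "b": np.zeros(c_out, dtype=F32),
        }

    def _geometry(self, H: int, W: int):
        if self.padding == "same":
            pt, pb = _same_pads(H, self.F, self.S)
            pl, pr = _same_pads(W, self.F, self.S)
            ho, wo = -(-H // self.S), -(-W // self.S)
        else:
            p = int(self.padding)
            pt = pb = pl = pr = p
            ho = (H - self.F + 2 * p) // self.S + 1
            wo = (W - self.F + 2 * p) // self.S + 1
        return (pt, pb, pl, pr), ho, wo

    def forward(self, x, training=False):
        n, H, W, _ = x.shape
        (pt, pb, pl, pr), ho, wo = self._geometry(H, W)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(xp, self.F, self.S, ho, wo)
        self._cache = (cols, xp.shape, (pt, pl), (H, W))
        Wm = self.params["W"].reshape(-1, self.c_out)
        y = cols.reshape(n * ho * wo, -1) @ Wm + self.params["b"]
        return y.reshape(n, ho, wo, self.c_out)

    def backward(self, dout):
        cols, xp_shape, (pt, pl), (H, W) = self._cache
        n, ho, wo, _ = dout.shape
        dflat = dout.reshape(n * ho * wo, self.c_out)
        Wm = self.params["W"].reshape(-1, self.c_out)
        self.grads = {
            "W": (cols.reshape(n * ho * wo, -1).T @ dflat).reshape(self.params["W"].shape),
            "b": dflat.sum(axis=0),
        }
        dcols = (dflat @ Wm.T).reshape(n, ho, wo, self.F, self.F, self.c_in)
        dxp = _col_scatter(dcols, xp_shape, self.F, self.S)
        return dxp[:, pt : pt + H, pl : pl + W, :]


class ConvTranspose2D(Layer):
    """Transposed convolution with 'same' padding: (H, W) -> (H·S, W·S).

    Implemented as the adjoint of a stride-S 'same' convolution mapping the
    output grid back to the input grid, which reproduces the standard
    framework semantics exactly.
    """

    def __init__(self, c_in: int, c_out: int, F: int, S: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.F, self.S = F, S
        self.c_in, self.c_out = c_in, c_out
        fan_in, fan_out = F * F * c_in, F * F * c_out
        self.params = {
            "W": _glorot(rng, (F, F, c_out, c_in), fan_in, fan_out),
            "b": np.zeros(c_out, dtype=F32),
        }

    def forward(self, x, training=False):
        n, H, W, _ = x.shape
        Ho, Wo = H * self.S, W * self.S
        pt, pb = _same_pads(Ho, self.F, self.S)
        pl, pr = _same_pads(Wo, self.F, self.S)
        Wm = self.params["W"].reshape(-1, self.c_in)  # (F*F*c_out, c_in)
        dcols = (x.reshape(n * H * W, self.c_in) @ Wm.T).reshape(
            n, H, W, self.F, self.F, self.c_out
        )
        yp = _col_scatter(dcols, (n, Ho + pt + pb, Wo + pl + pr, self.c_out), self.F, self.S)
        y = yp[:, pt : pt + Ho, pl : pl + Wo, :] + self.params["b"]
        self._cache = (x, (pt, pb, pl, pr), (Ho, Wo))
        return y

    def backward(self, dout):
        x, (pt, pb, pl, pr), (Ho, Wo) = self._cache
        n, H, W, _ = x.shape
        dp = np.pad(dout, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(dp, self.F, self.S, H, W)  # (n, H, W, F, F, c_out)
        cols_flat = cols.reshape(n * H * W, -1)
        self.grads = {
            "W": (cols_flat.T @ x.reshape(n * H * W, self.c_in)).reshape(self.params["W"].shape),
            "b": dout.sum(axis=(0, 1, 2)),
        }
        Wm = self.params["W"].reshape(-1, self.c_in)
        return (cols_flat @ Wm).reshape(n, H, W, self.c_in)


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(channels, dtype=F32),
            "beta": np.zeros(channels, dtype=F32),
        }
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads = {
            "gamma": (dout * xhat).sum(axis=axes),
            "beta": dout.sum(axis=axes),
        }
        dxhat = dout * self.params["gamma"]
        return inv * (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes) / m
        )


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(alpha=0.0)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2D(Layer):
    def __init__(self, F: int, S: int) -> None:
        super().__init__()
        self.F, self.S = F, S

    def forward(self, x, training=False):
        n, H, W, C = x.shape
        ho = (H - self.F) // self.S + 1
        wo = (W - self.F) // self.S + 1
        cols = _im2col(x, self.F, self.S, ho, wo).reshape(n, ho, wo, self.F * self.F, C)
        self._argmax = cols.argmax(axis=3)
        self._shape = x.shape
        return cols.max(axis=3)

    def backward(self, dout):
        n, ho, wo, _ = dout.shape
        C = self._shape[-1]
        dcols = np.zeros((n, ho, wo, self.F * self.F, C), dtype=dout.dtype)
        np.put_along_axis(dcols, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dcols = dcols.reshape(n, ho, wo, self.F, self.F, C)
        return _col_scatter(dcols, self._shape, self.F, self.S)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: Sequence[int]) -> None:
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x, training=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)


class Sequential:
    """Plain layer stack with shared forward/backward and a state dict."""

    def __init__(self, layers: Iterable[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        """Flat list of (layer_idx, name, array) references."""
        return [
            (i, k, layer.params[k])
            for i, layer in enumerate(self.layers)
            for k in sorted(layer.params)
        ]

    def gradients(self):
        return [
            (i, k, layer.grads[k])
            for i, layer in enumerate(self.layers)
            for k in sorted(layer.params)
        ]

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.grads = {k: np.zeros_like(v) for k, v in layer.params.items()}

    def add_grads(self, stash) -> None:
        for (i, k, g), (_, _, extra) in zip(self.gradients(), stash):
            g += extra

    def copy_grads(self):
        return [(i, k, g.copy()) for i, k, g in self.gradients()]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"{i}.{k}"] = v
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"{i}.{k}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


# --------------------------------------------------------------------------
# Optimizers — the five adaptive solvers of the hyperparameter grid.
# Defaults follow the common framework conventions for each solver.


class _Optimizer:
    def __init__(self, lr: float) -> None:
        self.lr = lr
        self.state: dict[tuple, dict] = {}

    def step(self, model: Sequential) -> None:
        for (i, k, p), (_, _, g) in zip(model.parameters(), model.gradients()):
            slot = self.state.setdefault((i, k), self._init(p))
            self._update(p, g.astype(p.dtype), slot)

    def _init(self, p):  # pragma: no cover
        raise NotImplementedError

    def _update(self, p, g, slot):  # pragma: no cover
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps

    def _init(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p), "t": 0}

    def _update(self, p, g, s):
        s["t"] += 1
        s["m"] = self.b1 * s["m"] + (1 - self.b1) * g
        s["v"] = self.b2 * s["v"] + (1 - self.b2) * g * g
        mhat = s["m"] / (1 - self.b1 ** s["t"])
        vhat = s["v"] / (1 - self.b2 ** s["t"])
        p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class AdaMax(Adam):
    def __init__(self, lr: float = 2e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        super().__init__(lr, beta1, beta2, eps)

    def _update(self, p, g, s):
        s["t"] += 1
        s["m"] = self.b1 * s["m"] + (1 - self.b1) * g
        s["v"] = np.maximum(self.b2 * s["v"], np.abs(g))
        p -= (self.lr / (1 - self.b1 ** s["t"]) * s["m"] / (s["v"] + self.eps)).astype(p.dtype)


class RMSprop(_Optimizer):
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _init(self, p):
        return {"v": np.zeros_like(p)}

    def _update(self, p, g, s):
        s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
        p -= (self.lr * g / (np.sqrt(s["v"]) + self.eps)).astype(p.dtype)


class AdaGrad(_Optimizer):
    def __init__(self, lr: float = 1e-2, eps: float = 1e-7):
        super().__init__(lr)
        self.eps = eps

    def _init(self, p):
        return {"v": np.zeros_like(p)}

    def _update(self, p, g, s):
        s["v"] += g * g
        p -= (self.lr * g / (np.sqrt(s["v"]) + self.eps)).astype(p.dtype)


class AdaDelta(_Optimizer):
    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _init(self, p):
        return {"v": np.zeros_like(p), "u": np.zeros_like(p)}

    def _update(self, p, g, s):
        s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
        dx = np.sqrt(s["u"] + self.eps) / np.sqrt(s["v"] + self.eps) * g
        s["u"] = self.rho * s["u"] + (1 - self.rho) * dx * dx
        p -= (self.lr * dx).astype(p.dtype)


SOLVERS = {
    "Adam": Adam,
    "RMSprop": RMSprop,
    "AdaDelta": AdaDelta,
    "AdaMax": AdaMax,
    "AdaGrad": AdaGrad,
}


def make_optimizer(name: str, lr: float | None = None) -> _Optimizer:
    """Instantiate one of the grid solvers by name (case-sensitive)."""
    if name not in SOLVERS:
        raise ValueError(f"unknown solver {name!r}; choose from {sorted(SOLVERS)}")
    return SOLVERS[name]() if lr is None else SOLVERS[name](lr)


# --------------------------------------------------------------------------
# Loss heads


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy (nats) and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
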