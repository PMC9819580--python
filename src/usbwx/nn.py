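"""Minimal convolutional-network engine on numpy.

Implements exactly the pieces the restoration models need: 'same' 2D
convolution (with dilation), batch normalization, 2x2 max pooling and
nearest-neighbour upsampling, dropout, concatenation/addition skip
connections, and the Adam optimizer.  Networks are small DAGs evaluated in
insertion order; each layer implements ``forward`` and ``backward`` and owns
its :class:`Param` objects, from which exact trainable / non-trainable
parameter accounting follows.

Arrays are channels-last float32 batches of shape ``(N, H, W, C)``.
Gradients are accumulated per parameter between ``zero_grad`` calls.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv2D", "FixedConv2D", "BatchNorm", "ReLU",
    "MaxPool2", "Upsample2", "Dropout", "Concat", "Add", "Network", "Adam",
]


class Param:
    """A tensor parameter with a gradient buffer and a trainable flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: stateless unless it declares params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, *xs: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray):
        raise NotImplementedError


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """'Same' 2D convolution with odd kernel, stride 1 and optional dilation.

    Weight layout ``(k, k, c_in, c_out)``.  Forward/backward are expressed as
    k*k slice matmuls against zero-padded inputs, which keeps memory bounded
    and routes the arithmetic through BLAS.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, dilation: int = 1,
                 bias: bool = True, trainable: bool = True,
                 rng: np.random.Generator | None = None, name: str = ""):
        if kernel % 2 == 0:
            raise ValueError("only odd kernels are supported")
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, kernel, dilation
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        w = glorot_uniform((kernel, kernel, c_in, c_out), fan_in, fan_out, rng)
        self.w = Param(w, trainable=trainable, name=f"{name}.w")
        self.b = Param(np.zeros(c_out, np.float32), trainable=trainable,
                       name=f"{name}.b") if bias else None
        self._xpad: np.ndarray | None = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.d * (self.k - 1) // 2
        if h + 2 * p < self.d * (self.k - 1) + 1 or w + 2 * p < self.d * (self.k - 1) + 1:
            raise ValueError("kernel support exceeds padded input")
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.zeros((n, h, w, self.c_out), np.float32)
        wv = self.w.value
        for i in range(self.k):
            for j in range(self.k):
                sl = xp[:, i * self.d:i * self.d + h, j * self.d:j * self.d + w, :]
                out += np.ascontiguousarray(sl) @ wv[i, j]
        if self.b is not None:
            out += self.b.value
        self._xpad = xp
        self._hw = (h, w)
        return out

    def backward(self, dy):
        h, w = self._hw
        xp = self._xpad
        dxp = np.zeros_like(xp)
        wv = self.w.value
        dy64 = dy.reshape(-1, self.c_out)
        for i in range(self.k):
            for j in range(self.k):
                sl = np.ascontiguousarray(
                    xp[:, i * self.d:i * self.d + h, j * self.d:j * self.d + w, :])
                self.w.grad[i, j] += sl.reshape(-1, self.c_in).T @ dy64
                dxp[:, i * self.d:i * self.d + h, j * self.d:j * self.d + w, :] += dy @ wv[i, j].T
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 1, 2))
        p = self.d * (self.k - 1) // 2
        self._xpad = None
        if p == 0:
            return dxp
        return dxp[:, p:p + h, p:p + w, :]


class FixedConv2D(Conv2D):
    """Convolution with externally supplied, frozen weights (e.g. edge banks)."""

    def __init__(self, weights: np.ndarray, bias: np.ndarray | None = None,
                 dilation: int = 1, name: str = ""):
        k, k2, c_in, c_out = weights.shape
        if k != k2:
            raise ValueError("kernel must be square")
        Layer.__init__(self)
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, k, dilation
        self.w = Param(weights, trainable=False, name=f"{name}.w")
        self.b = (Param(bias, trainable=False, name=f"{name}.b")
                  if bias is not None else None)
        self._xpad = None


class BatchNorm(Layer):
    """Per-channel batch normalization (momentum/eps follow Keras defaults).

    gamma/beta are trainable; the moving mean/variance pair is tracked as
    non-trainable state and used at inference time.
    """

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-3,
                 name: str = ""):
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(c, np.float32), name=f"{name}.gamma")
        self.beta = Param(np.zeros(c, np.float32), name=f"{name}.beta")
        self.moving_mean = Param(np.zeros(c, np.float32), trainable=False,
                                 name=f"{name}.moving_mean")
        self.moving_var = Param(np.ones(c, np.float32), trainable=False,
                                name=f"{name}.moving_var")

    def params(self):
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.moving_mean.value = (m * self.moving_mean.value
                                      + (1 - m) * mu).astype(np.float32)
            self.moving_var.value = (m * self.moving_var.value
                                     + (1 - m) * var).astype(np.float32)
        else:
            mu = self.moving_mean.value
            var = self.moving_var.value
        ivar = 1.0 / np.sqrt(var + self.eps)
        xc = x - mu
        xhat = xc * ivar
        self._cache = (xc, xhat, ivar, training, x.shape)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dy):
        xc, xhat, ivar, training, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        g = self.gamma.value
        if not training:
            return dy * g * ivar
        dxhat = dy * g
        # standard batch-norm backward through the batch statistics
        dvar = (dxhat * xc).sum(axis=(0, 1, 2)) * (-0.5) * ivar ** 3
        dmu = (-(dxhat * ivar).sum(axis=(0, 1, 2))
               + dvar * (-2.0 / m) * xc.sum(axis=(0, 1, 2)))
        return (dxhat * ivar + dvar * 2.0 * xc / m + dmu / m).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H and W must be even."""

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(n, h, w, c)


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = self._shape
        return dy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class Concat(Layer):
    def forward(self, *xs, training=False, rng=None):
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        return np.concatenate(xs, axis=-1)

    def backward(self, dy):
        return tuple(np.ascontiguousarray(a)
                     for a in np.split(dy, self._splits, axis=-1))


class Add(Layer):
    def forward(self, *xs, training=False, rng=None):
        self._n = len(xs)
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out

    def backward(self, dy):
        return tuple(dy for _ in range(self._n))


class Network:
    """A small DAG of layers.

    Node 0 is the external input; ``add(layer, *parents)`` appends a node and
    returns its id.  ``forward`` evaluates nodes in insertion order (parents
    must precede children), ``backward`` propagates in reverse and accumulates
    parameter gradients.
    """

    def __init__(self, seed: int = 0):
        self.nodes: list[tuple[Layer | None, tuple[int, ...]]] = [(None, ())]
        self.rng = np.random.default_rng(seed)
        self.build_rng = np.random.default_rng(seed)

    def add(self, layer: Layer, *parents: int) -> int:
        if not parents:
            parents = (len(self.nodes) - 1,)
        self.nodes.append((layer, tuple(parents)))
        return len(self.nodes) - 1

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for layer, _ in self.nodes[1:]:
            out.extend(layer.params())
        return out

    def count_params(self) -> tuple[int, int, int]:
        """(total, trainable, non_trainable) over all parameter tensors."""
        tr = sum(p.size for p in self.params() if p.trainable)
        nt = sum(p.size for p in self.params() if not p.trainable)
        return tr + nt, tr, nt

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        outs: list[np.ndarray | None] = [np.asarray(x, np.float32)]
        for layer, parents in self.nodes[1:]:
            ins = [outs[p] for p in parents]
            outs.append(layer.forward(*ins, training=training, rng=self.rng))
        self._outs = outs
        return outs[-1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grads: list[np.ndarray | None] = [None] * len(self.nodes)
        grads[-1] = np.asarray(dy, np.float32)
        for idx in range(len(self.nodes) - 1, 0, -1):
            layer, parents = self.nodes[idx]
            if grads[idx] is None:
                continue
            dxs = layer.backward(grads[idx])
            if not isinstance(dxs, tuple):
                dxs = (dxs,)
            for p, dx in zip(parents, dxs):
                if grads[p] is None:
                    grads[p] = dx.copy()
                else:
                    grads[p] += dx
        return grads[0]

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        ps = self.params()
        if len(state) != len(ps):
            raise ValueError("checkpoint does not match network structure")
        for i, p in enumerate(ps):
            v = np.asarray(state[f"p{i}"], np.float32)
            if v.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value = v


class Adam:
    """Adam with Keras-style defaults (epsilon 1e-7, no weight decay)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state_dict(self) -> dict:
        out = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for i in range(len(self.m)):
            self.m[i] = np.asarray(state[f"m{i}"], np.float32)
            self.v[i] = np.asarray(state[f"v{i}"], np.float32)
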