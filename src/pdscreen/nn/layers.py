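"""Layers with explicit forward/backward passes.

Conventions
-----------
* 1-D data is ``(B, C, L)``; 2-D data is ``(B, C, H, W)``; dense data is
  ``(B, D)``; LSTM sequences are ``(B, T, D)``.
* ``forward(x, train=...)`` caches intermediates on ``self``;
  ``backward(grad)`` returns the gradient w.r.t. the input and adds parameter
  gradients into ``Param.grad``.  A layer instance therefore handles one
  forward/backward pair at a time (plain SGD-style training loops).
* Learned convolutions use cross-correlation, the standard framework
  convention; the flipped-kernel textbook convolution is available as a pure
  function in :mod:`pdscreen.speech` and serves as the test oracle.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable array plus its gradient accumulator."""

    __slots__ = ("data", "grad", "name", "is_weight")

    def __init__(self, data: np.ndarray, name: str = "", is_weight: bool = True):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name
        # is_weight: included in L2 regularization (biases / norm params are not)
        self.is_weight = is_weight


class Layer:
    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "dense"):
        self.W = Param(he_init(rng, (d_in, d_out), d_in), f"{name}.W")
        self.b = Param(np.zeros(d_out), f"{name}.b", is_weight=False) if bias else None

    def forward(self, x, train: bool = False):
        self._x = x
        out = x @ self.W.data
        if self.b is not None:
            out = out + self.b.data
        return out

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data.T

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity when ``train=False`` or ``p == 0``."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Conv1d(Layer):
    """Valid cross-correlation over ``(B, C_in, L)`` with stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, name: str = "conv1d"):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        fan_in = c_in * kernel
        self.W = Param(he_init(rng, (c_out, c_in, kernel), fan_in), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b", is_weight=False)

    def out_length(self, L: int) -> int:
        return (L - self.kernel) // self.stride + 1

    def forward(self, x, train: bool = False):
        B, C, L = x.shape
        if L < self.kernel:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel}")
        Lp = self.out_length(L)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        win = win[:, :, :: self.stride]  # (B, C, Lp, K)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * Lp, C * self.kernel)
        self._cols, self._shape = cols, (B, C, L, Lp)
        Wm = self.W.data.reshape(self.c_out, -1)
        out = cols @ Wm.T + self.b.data
        return np.ascontiguousarray(out.reshape(B, Lp, self.c_out).transpose(0, 2, 1))

    def backward(self, grad):
        B, C, L, Lp = self._shape
        g = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * Lp, self.c_out)
        self.W.grad += (g.T @ self._cols).reshape(self.W.data.shape)
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.data.reshape(self.c_out, -1)).reshape(B, Lp, C, self.kernel)
        dx = np.zeros((B, C, L), dtype=grad.dtype)
        for k in range(self.kernel):
            dx[:, :, k : k + self.stride * Lp : self.stride] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dx

    def params(self):
        return [self.W, self.b]


class MaxPool1d(Layer):
    """Temporal max pooling; kernel == stride (non-overlapping), floor semantics."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x, train: bool = False):
        B, C, L = x.shape
        Lp = L // self.kernel
        xt = x[:, :, : Lp * self.kernel].reshape(B, C, Lp, self.kernel)
        self._arg = xt.argmax(axis=3)
        self._shape = (B, C, L, Lp)
        return xt.max(axis=3)

    def backward(self, grad):
        B, C, L, Lp = self._shape
        dx = np.zeros((B, C, Lp, self.kernel), dtype=grad.dtype)
        bi, ci, pi = np.ogrid[:B, :C, :Lp]
        dx[bi, ci, pi, self._arg] = grad
        out = np.zeros((B, C, L), dtype=grad.dtype)
        out[:, :, : Lp * self.kernel] = dx.reshape(B, C, Lp * self.kernel)
        return out


class Conv2d(Layer):
    """Cross-correlation over ``(B, C, H, W)`` with stride and zero padding.

    Implemented as shift-and-add: one batched channel-mixing matmul per
    kernel offset, which keeps every matmul operand contiguous (much faster
    than im2col gathers for the small channel counts used here).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, bias: bool = True, name: str = "conv2d"):
        self.c_in, self.c_out = c_in, c_out
        self.kh = self.kw = kernel
        self.stride, self.pad = stride, pad
        fan_in = c_in * kernel * kernel
        self.W = Param(he_init(rng, (c_out, c_in, kernel, kernel), fan_in), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b", is_weight=False) if bias else None

    def forward(self, x, train: bool = False):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        B, C, H, W = x.shape
        if self.kh > H or self.kw > W:
            raise ValueError("kernel larger than (padded) input")
        s = self.stride
        Ho = (H - self.kh) // s + 1
        Wo = (W - self.kw) // s + 1
        N = Ho * Wo
        out = np.zeros((B, self.c_out, N), dtype=x.dtype)
        self._xs = []
        Wd = self.W.data
        for j in range(self.kh):
            for k in range(self.kw):
                xs = np.ascontiguousarray(
                    x[:, :, j : j + s * Ho : s, k : k + s * Wo : s]
                ).reshape(B, C, N)
                self._xs.append(xs)
                out += Wd[:, :, j, k] @ xs
        if self.b is not None:
            out += self.b.data[None, :, None]
        self._shape = (B, C, H, W, Ho, Wo)
        return out.reshape(B, self.c_out, Ho, Wo)

    def backward(self, grad):
        B, C, H, W, Ho, Wo = self._shape
        s = self.stride
        g = np.ascontiguousarray(grad).reshape(B, self.c_out, Ho * Wo)
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2))
        dx = np.zeros((B, C, H, W), dtype=grad.dtype)
        gT = g.transpose(0, 2, 1)  # (B, N, O)
        idx = 0
        for j in range(self.kh):
            for k in range(self.kw):
                xs = self._xs[idx]
                idx += 1
                self.W.grad[:, :, j, k] += np.matmul(xs, gT).sum(axis=0).T
                ds = self.W.data[:, :, j, k].T @ g  # (B, C, N)
                dx[:, :, j : j + s * Ho : s, k : k + s * Wo : s] += \
                    ds.reshape(B, C, Ho, Wo)
        self._xs = []
        if self.pad:
            dx = dx[:, :, self.pad : H - self.pad, self.pad : W - self.pad]
        return dx

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, train: bool = False):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                       constant_values=-np.inf)
        B, C, H, W = x.shape
        k, s = self.kernel, self.stride
        Ho = (H - k) // s + 1
        Wo = (W - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = np.ascontiguousarray(win[:, :, ::s, ::s]).reshape(B, C, Ho, Wo, k * k)
        self._arg = win.argmax(axis=4)
        self._shape = (B, C, H, W, Ho, Wo)
        return win.max(axis=4)

    def backward(self, grad):
        B, C, H, W, Ho, Wo = self._shape
        k, s = self.kernel, self.stride
        dx = np.zeros((B, C, H, W), dtype=grad.dtype)
        jj, kk = np.divmod(self._arg, k)  # offsets within window
        bi, ci, hi, wi = np.indices((B, C, Ho, Wo), sparse=False)
        np.add.at(dx, (bi, ci, hi * s + jj, wi * s + kk), grad)
        if self.pad:
            dx = dx[:, :, self.pad : H - self.pad, self.pad : W - self.pad]
        return dx


class GlobalAvgPool2d(Layer):
    """Per-channel spatial mean: (B, C, H, W) -> (B, C)."""

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma", is_weight=False)
        self.beta = Param(np.zeros(channels), f"{name}.beta", is_weight=False)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train: bool = False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad):
        xhat, inv, train, shape = self._cache
        B, C, H, W = shape
        n = B * H * W
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not train:
            return g * inv[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (n * g - gsum - xhat * gx)

    def params(self):
        return [self.gamma, self.beta]


class LSTM(Layer):
    """Single LSTM layer over ``(B, T, D)`` returning the full hidden sequence.

    Gate pre-activations use the packed weight ``W`` of shape ``(H + D, 4H)``
    acting on the concatenation ``[h_{t-1}, x_t]`` (hidden part first), split
    in the order input, forget, candidate, output.  States start at zero.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 name: str = "lstm"):
        self.d_in, self.hidden = d_in, hidden
        scale = 1.0 / np.sqrt(hidden)
        self.W = Param(rng.uniform(-scale, scale, size=(hidden + d_in, 4 * hidden)),
                       f"{name}.W")
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias init
        self.b = Param(b, f"{name}.b", is_weight=False)

    def forward(self, x, train: bool = False):
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        self._cache = []
        out = np.empty((B, T, H), dtype=x.dtype)
        for t in range(T):
            z = np.concatenate([h, x[:, t]], axis=1)
            a = z @ self.W.data + self.b.data
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h = o * tanh_c
            self._cache.append((z, i, f, g, o, c, tanh_c))
            c = c_new
            out[:, t] = h
        self._T, self._B = T, B
        return out

    def backward(self, grad):
        B, T, H = self._B, self._T, self.hidden
        dh_next = np.zeros((B, H), dtype=grad.dtype)
        dc_next = np.zeros((B, H), dtype=grad.dtype)
        dx = np.empty((B, T, self.d_in), dtype=grad.dtype)
        for t in range(T - 1, -1, -1):
            z, i, f, g, o, c_prev, tanh_c = self._cache[t]
            dh = grad[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1 - tanh_c ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.W.grad += z.T @ da
            self.b.grad += da.sum(axis=0)
            dz = da @ self.W.data.T
            dh_next = dz[:, :H]
            dx[:, t] = dz[:, H:]
            dc_next = dc * f
        return dx

    def params(self):
        return [self.W, self.b]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class ResidualBlock(Layer):
    """Two 3x3 conv/BN pairs with identity (or projection) skip: H(x) = F(x) + x.

    When the stage width changes or ``stride > 1``, the skip path is a 1x1
    stride-matched projection convolution (+BN); otherwise it is the identity,
    so zeroing the residual-branch weights makes the block an exact identity
    map.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, batch_norm: bool = True, bias: bool = False,
                 name: str = "res"):
        def bn(ch, tag):
            return [BatchNorm2d(ch, name=f"{name}.{tag}")] if batch_norm else []

        self.branch = Sequential(
            Conv2d(c_in, c_out, 3, rng, stride=stride, pad=1, bias=bias,
                   name=f"{name}.conv1"),
            *bn(c_out, "bn1"),
            ReLU(),
            Conv2d(c_out, c_out, 3, rng, stride=1, pad=1, bias=bias,
                   name=f"{name}.conv2"),
            *bn(c_out, "bn2"),
        )
        if stride != 1 or c_in != c_out:
            self.skip = Sequential(
                Conv2d(c_in, c_out, 1, rng, stride=stride, pad=0, bias=bias,
                       name=f"{name}.proj"),
                *bn(c_out, "bnp"),
            )
        else:
            self.skip = None
        self.relu = ReLU()

    def forward(self, x, train: bool = False):
        fx = self.branch.forward(x, train=train)
        sx = self.skip.forward(x, train=train) if self.skip is not None else x
        return self.relu.forward(fx + sx, train=train)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        dbranch = self.branch.backward(grad)
        dskip = self.skip.backward(grad) if self.skip is not None else grad
        return dbranch + dskip

    def params(self):
        out = self.branch.params()
        if self.skip is not None:
            out.extend(self.skip.params())
        return out
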