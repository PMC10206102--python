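"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the Restore-CycleGAN needs: strided
convolution and transposed convolution (im2col/col2im), instance
normalization, leaky/plain rectification, tanh, concatenation, elementwise
arithmetic, absolute value, square and mean — plus an Adam optimizer.
Tensors are NCHW float arrays. Gradients are validated against numerical
derivatives in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Tensor", "astensor", "concat", "mean", "absval", "square",
    "leaky_relu", "relu", "tanh", "instance_norm", "pad2d", "crop2d",
    "conv2d", "conv_transpose2d", "Conv2d", "ConvTranspose2d", "Adam",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "requires_grad", "_backward")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data)
        self.parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: loss graphs can be hundreds of nodes deep
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # --- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def _bw():
            _acc(self, _unbroadcast(out.grad, self.data.shape))
            _acc(other, _unbroadcast(out.grad, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def _bw():
            _acc(self, -out.grad)
        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def _bw():
            _acc(self, _unbroadcast(out.grad * other.data, self.data.shape))
            _acc(other, _unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _acc(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# --- reductions and pointwise nonlinearities ------------------------------

def mean(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.asarray(x.data.mean()), (x,))

    def _bw():
        _acc(x, np.full_like(x.data, out.grad / x.data.size))
    out._backward = _bw
    return out


def square(x: Tensor) -> Tensor:
    x = astensor(x)
    return x * x


def absval(x: Tensor) -> Tensor:
    x = astensor(x)
    out = Tensor(np.abs(x.data), (x,))

    def _bw():
        _acc(x, out.grad * np.sign(x.data))
    out._backward = _bw
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, slope * x.data), (x,))

    def _bw():
        _acc(x, out.grad * np.where(x.data > 0, 1.0, slope))
    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    return leaky_relu(x, 0.0)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))

    def _bw():
        _acc(x, out.grad * (1.0 - y * y))
    out._backward = _bw
    return out


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=axis), (a, b))
    na = a.data.shape[axis]

    def _bw():
        ga, gb = np.split(out.grad, [na], axis=axis)
        _acc(a, ga)
        _acc(b, gb)
    out._backward = _bw
    return out


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes (no affine)."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    out = Tensor(y, (x,))

    def _bw():
        g = out.grad
        gm = g.mean(axis=(2, 3), keepdims=True)
        gym = (g * y).mean(axis=(2, 3), keepdims=True)
        _acc(x, inv * (g - gm - y * gym))
    out._backward = _bw
    return out


def pad2d(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the spatial axes; the pad is split floor-low / remainder-high."""
    lo_h, hi_h = pad_h // 2, pad_h - pad_h // 2
    lo_w, hi_w = pad_w // 2, pad_w - pad_w // 2
    out = Tensor(np.pad(x.data, ((0, 0), (0, 0), (lo_h, hi_h), (lo_w, hi_w))), (x,))

    def _bw():
        h, w = x.data.shape[2:]
        _acc(x, out.grad[:, :, lo_h:lo_h + h, lo_w:lo_w + w])
    out._backward = _bw
    return out


def crop2d(x: Tensor, lo_h: int, h: int, lo_w: int, w: int) -> Tensor:
    out = Tensor(x.data[:, :, lo_h:lo_h + h, lo_w:lo_w + w], (x,))

    def _bw():
        g = np.zeros_like(x.data)
        g[:, :, lo_h:lo_h + h, lo_w:lo_w + w] = out.grad
        _acc(x, g)
    out._backward = _bw
    return out


# --- convolution plumbing --------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = as_strided(xp, (b, c, ho, wo, k, k),
                     (s0, s1, s2 * stride, s3 * stride, s2, s3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(b, ho * wo, c * k * k), ho, wo


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    b, c, h, w = shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride,
                kj:kj + stride * wo:stride] += d6[:, :, :, :, ki, kj]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor,
           stride: int = 2, pad: int = 1) -> Tensor:
    """2-D convolution; ``weight`` is (Cout, Cin, k, k), ``bias`` (Cout,)."""
    b, c, h, w = x.data.shape
    cout, cin, k, _ = weight.data.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {cin}")
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wm = weight.data.reshape(cout, -1)
    out_flat = cols @ wm.T + bias.data
    out = Tensor(out_flat.transpose(0, 2, 1).reshape(b, cout, ho, wo),
                 (x, weight, bias))

    def _bw():
        g = out.grad.reshape(b, cout, ho * wo).transpose(0, 2, 1)
        _acc(bias, g.sum(axis=(0, 1)))
        _acc(weight, np.einsum("blo,blk->ok", g, cols).reshape(weight.data.shape))
        if x.requires_grad:
            _acc(x, _col2im(g @ wm, x.data.shape, k, stride, pad, ho, wo))
    out._backward = _bw
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor,
                     stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed convolution; ``weight`` is (Cin, Cout, k, k)."""
    b, c, h, w = x.data.shape
    cin, cout, k, _ = weight.data.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {cin}")
    ho = (h - 1) * stride - 2 * pad + k
    wo = (w - 1) * stride - 2 * pad + k
    xt = x.data.transpose(0, 2, 3, 1).reshape(b, h * w, c)
    wm = weight.data.reshape(cin, cout * k * k)
    scatter = xt @ wm  # (b, h*w, cout*k*k)
    out_data = _col2im(scatter, (b, cout, ho, wo), k, stride, pad, h, w)
    out = Tensor(out_data + bias.data[None, :, None, None], (x, weight, bias))

    def _bw():
        g = out.grad
        _acc(bias, g.sum(axis=(0, 2, 3)))
        gcols, gh, gw = _im2col(g, k, stride, pad)
        assert gh == h and gw == w
        _acc(weight, np.einsum("bli,blj->ij", xt, gcols).reshape(weight.data.shape))
        if x.requires_grad:
            dx = (gcols @ wm.T).reshape(b, h, w, c).transpose(0, 3, 1, 2)
            _acc(x, dx)
    out._backward = _bw
    return out


# --- layers and optimizer ---------------------------------------------------

class Conv2d:
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 init_sd: float = 0.02, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(rng.normal(0.0, init_sd, (cout, cin, k, k)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.out_channels = cout

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)

    def parameters(self):
        return [self.weight, self.bias]


class ConvTranspose2d:
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 init_sd: float = 0.02, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(rng.normal(0.0, init_sd, (cin, cout, k, k)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.out_channels = cout

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)

    def parameters(self):
        return [self.weight, self.bias]


class Adam:
    """Adam optimizer; defaults match the training recipe (lr 2e-4, beta1 0.5)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
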