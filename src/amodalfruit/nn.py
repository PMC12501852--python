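"""Reverse-mode automatic differentiation and neural-network layers on numpy.

The segmentation network in this package runs on this small engine: a
:class:`Tensor` records the operations applied to it and ``backward()``
propagates gradients through the recorded graph in reverse topological
order.  Only the operations the network needs are provided — dense and
convolutional layers (with stride, padding and dilation), a 2x2 stride-2
transposed convolution, nearest-neighbour upsampling, RoIAlign with
bilinear sampling, reductions, softmax, and the detection losses
(cross-entropy, binary cross-entropy with logits, smooth L1).

All arithmetic is float64; arrays are kept in (B, C, H, W) layout.
Gradients of the custom ops are covered by finite-difference checks in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x2",
    "Linear",
    "GroupNorm",
    "ReLU",
    "SGD",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- elementwise arithmetic ---------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    # -- nonlinearities ------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bwd
        return out

    def softmax(self, axis: int) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = bwd
        return out

    # -- reductions & shape --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        out = Tensor(m if keepdims else np.squeeze(m, axis), _prev=(self,))
        # ties split gradient equally, matching the subgradient convention
        mask = (self.data == m)
        counts = mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(mask * g / counts)

        out._backward = bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Convolution ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, square kernel.

    Implemented as a sum over kernel offsets of strided tensordots — no
    im2col materialisation, which keeps small-feature-map training cheap.
    """
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    eff_h = (kh - 1) * dilation + 1
    eff_w = (kw - 1) * dilation + 1
    Ho = (Hp - eff_h) // stride + 1
    Wo = (Wp - eff_w) // stride + 1
    out_data = np.zeros((B, O, Ho, Wo))
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i * dilation: i * dilation + stride * (Ho - 1) + 1: stride,
                          j * dilation: j * dilation + stride * (Wo - 1) + 1: stride]
            # (O,C)x(B,C,Ho,Wo) -> (O,B,Ho,Wo)
            out_data += np.tensordot(weight.data[:, :, i, j], patch,
                                     axes=(1, 1)).transpose(1, 0, 2, 3)
    prev = (x, weight) + ((bias,) if bias is not None else ())
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)
    out = Tensor(out_data, _prev=prev)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = weight.requires_grad
        if not (need_x or need_w):
            return
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(weight.data) if need_w else None
        for i in range(kh):
            for j in range(kw):
                rs = slice(i * dilation, i * dilation + stride * (Ho - 1) + 1, stride)
                cs = slice(j * dilation, j * dilation + stride * (Wo - 1) + 1, stride)
                if need_w:
                    patch = xp[:, :, rs, cs]
                    gw[:, :, i, j] += np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                if need_x:
                    gxp[:, :, rs, cs] += np.tensordot(weight.data[:, :, i, j], g,
                                                      axes=(0, 1)).transpose(1, 0, 2, 3)
        if need_w:
            weight._accum(gw)
        if need_x:
            if padding:
                gxp = gxp[:, :, padding:Hp - padding, padding:Wp - padding]
            x._accum(gxp)

    out._backward = bwd
    return out


def conv_transpose2x2(x: Tensor, weight: Tensor, bias) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (no overlap).

    weight layout: (C_in, C_out, 2, 2); doubles the spatial size exactly.
    """
    B, C, H, W = x.data.shape
    Ci, O, _, _ = weight.data.shape
    if Ci != C:
        raise ValueError("conv_transpose2x2 channel mismatch")
    y = np.einsum("bchw,copq->bohpwq", x.data, weight.data).reshape(B, O, 2 * H, 2 * W)
    prev = (x, weight) + ((bias,) if bias is not None else ())
    if bias is not None:
        y = y + bias.data.reshape(1, O, 1, 1)
    out = Tensor(y, _prev=prev)

    def bwd(g):
        g6 = g.reshape(B, O, H, 2, W, 2)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            weight._accum(np.einsum("bchw,bohpwq->copq", x.data, g6))
        if x.requires_grad:
            x._accum(np.einsum("bohpwq,copq->bchw", g6, weight.data))

    out._backward = bwd
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(x,))
    B, C, H, W = x.data.shape

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def roi_align(feat: Tensor, boxes: np.ndarray, output_size: int,
              spatial_scale: float, sampling_ratio: int = 2) -> Tensor:
    """RoIAlign with bilinear sampling and average pooling per bin.

    ``feat``: (1, C, H, W); ``boxes``: (N, 4) in image pixels, half-open
    [x0, y0, x1, y1].  Returns (N, C, output_size, output_size).
    Box coordinates are treated as constants (no gradient), matching the
    usual two-stage-detector convention.
    """
    if feat.data.shape[0] != 1:
        raise ValueError("roi_align expects a single-image feature map")
    _, C, H, W = feat.data.shape
    boxes = np.asarray(boxes, dtype=np.float64) * spatial_scale
    N = boxes.shape[0]
    P, S = output_size, sampling_ratio
    if N == 0:
        return Tensor(np.zeros((0, C, P, P)))
    # sample-point grid: P*S points per axis per roi
    x0, y0, x1, y1 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    bw = np.maximum(x1 - x0, 1e-6) / P
    bh = np.maximum(y1 - y0, 1e-6) / P
    offs = (np.arange(P * S) + 0.5) / S  # in bin units
    sx = x0[:, None] + offs[None, :] * bw[:, None]  # (N, P*S)
    sy = y0[:, None] + offs[None, :] * bh[:, None]
    # bilinear neighbours, clipped to the map
    fx = np.clip(sx - 0.5, 0, W - 1)
    fy = np.clip(sy - 0.5, 0, H - 1)
    x_lo = np.floor(fx).astype(int)
    y_lo = np.floor(fy).astype(int)
    x_hi = np.minimum(x_lo + 1, W - 1)
    y_hi = np.minimum(y_lo + 1, H - 1)
    wx = fx - x_lo
    wy = fy - y_lo

    f = feat.data[0]  # (C,H,W)
    # gather rows/cols: result (N, C, P*S, P*S)
    def gather(yi, xi):
        return f[:, yi[:, :, None], xi[:, None, :]].transpose(1, 0, 2, 3)

    v = ((1 - wy)[:, None, :, None] * (1 - wx)[:, None, None, :] * gather(y_lo, x_lo)
         + (1 - wy)[:, None, :, None] * wx[:, None, None, :] * gather(y_lo, x_hi)
         + wy[:, None, :, None] * (1 - wx)[:, None, None, :] * gather(y_hi, x_lo)
         + wy[:, None, :, None] * wx[:, None, None, :] * gather(y_hi, x_hi))
    out_data = v.reshape(N, C, P, S, P, S).mean(axis=(3, 5))
    out = Tensor(out_data, _prev=(feat,))

    def bwd(g):
        if not feat.requires_grad:
            return
        gs = (g[:, :, :, None, :, None] / (S * S) *
              np.ones((1, 1, 1, S, 1, S))).reshape(len(boxes), C, P * S, P * S)
        gf = np.zeros_like(f)
        for n in range(len(boxes)):
            for (yy, xx, ww) in (
                (y_lo[n], x_lo[n], np.outer(1 - wy[n], 1 - wx[n])),
                (y_lo[n], x_hi[n], np.outer(1 - wy[n], wx[n])),
                (y_hi[n], x_lo[n], np.outer(wy[n], 1 - wx[n])),
                (y_hi[n], x_hi[n], np.outer(wy[n], wx[n])),
            ):
                contrib = gs[n] * ww[None, :, :]  # (C, PS, PS)
                np.add.at(gf, (slice(None), yy[:, None], xx[None, :]), contrib)
        feat._accum(gf[None])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if reduction == "mean":
        val, scale = loss.mean(), 1.0 / loss.size
    elif reduction == "sum":
        val, scale = loss.sum(), 1.0
    else:
        raise ValueError(reduction)
    out = Tensor(val, _prev=(logits,))
    sig = 1.0 / (1.0 + np.exp(-z))

    def bwd(g):
        if logits.requires_grad:
            logits._accum(g * scale * (sig - t))

    out._backward = bwd
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Softmax cross-entropy; logits (N, K), integer labels (N,)."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(labels)
    out = Tensor(-logp[np.arange(n), labels].mean(), _prev=(logits,))
    p = np.exp(logp)

    def bwd(g):
        if logits.requires_grad:
            gz = p.copy()
            gz[np.arange(n), labels] -= 1.0
            logits._accum(g * gz / n)

    out._backward = bwd
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Huber/smooth-L1 loss, mean reduction."""
    t = np.asarray(target, dtype=np.float64)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    out = Tensor(loss.mean(), _prev=(pred,))

    def bwd(g):
        if pred.requires_grad:
            grad = np.where(ad < beta, d / beta, np.sign(d))
            pred._accum(g * grad / d.size)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


class Sequential(Module):
    def __init__(self, *modules):
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, in_ch, out_ch, kernel, stride=1, padding=0,
                 dilation=1, bias=True):
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = _he_init(rng, (out_ch, in_ch, kernel, kernel),
                               in_ch * kernel * kernel)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation)


class ConvTranspose2x2(Module):
    def __init__(self, rng, in_ch, out_ch, bias=True):
        self.weight = _he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return conv_transpose2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, rng, in_f, out_f, bias=True):
        self.weight = _he_init(rng, (in_f, out_f), in_f)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True) if bias else None

    def forward(self, x):
        y = x.matmul(self.weight)
        return y + self.bias if self.bias is not None else y


class GroupNorm(Module):
    """Group normalisation — batch-size independent, so it suits batch 2."""

    def __init__(self, num_groups, num_channels, eps=1e-5):
        if num_channels % num_groups:
            raise ValueError("channels must divide into groups")
        self.g, self.eps = num_groups, eps
        self.weight = Tensor(np.ones(num_channels), requires_grad=True)
        self.bias = Tensor(np.zeros(num_channels), requires_grad=True)

    def forward(self, x):
        B, C, H, W = x.shape
        xg = x.reshape(B, self.g, C // self.g * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2.0).mean(axis=2, keepdims=True)
        norm = (xg - mu) * (var + self.eps) ** -0.5
        norm = norm.reshape(B, C, H, W)
        return norm * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SGD:
    """Plain SGD with momentum and optional gradient clipping."""

    def __init__(self, params, lr, momentum=0.9, clip=10.0):
        self.params = list(params)
        self.lr, self.momentum, self.clip = lr, momentum, clip
        self.vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.clip is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            scale = self.clip / total if total > self.clip else 1.0
        else:
            scale = 1.0
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad * scale
            p.data -= self.lr * v
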