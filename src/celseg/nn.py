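"""Minimal reverse-mode autodiff on numpy arrays for 3D segmentation networks.

Implements exactly the operations the U-Net and its losses need: 3D
convolution (stride 1 or 2, 'same' padding), instance normalization, PReLU,
nearest-neighbour upsampling, channel concatenation, sigmoid, and the
elementwise/reduction arithmetic used by the dice and focal losses.
Gradients are checked against central finite differences in the test suite.

All tensors are float64 ``(N, C, D, H, W)`` unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "conv3d",
    "instance_norm",
    "prelu",
    "sigmoid",
    "upsample_nearest",
    "concat",
    "clip",
    "log",
    "power",
    "Adam",
]


_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode).

    Inside the context no backward closures or cached buffers are kept, so
    large im2col matrices are freed as soon as each op returns.
    """

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    """A node in the computation tape.

    ``data`` is a numpy array; ``grad`` accumulates d(scalar loss)/d(data)
    after :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        if not _grad_enabled:
            parents, backward, requires_grad = (), None, False
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph traversal -------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative postorder; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        g = np.asarray(g)
        if g.shape != self.data.shape:  # reduce broadcast dimensions
            extra = g.ndim - self.data.ndim
            if extra > 0:
                g = g.sum(axis=tuple(range(extra)))
            axes = tuple(
                i for i, s in enumerate(self.data.shape) if s == 1 and g.shape[i] != 1
            )
            if axes:
                g = g.sum(axis=axes, keepdims=True)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(-g)

        return Tensor(self.data - other.data, parents=(self, other), backward=bwd)

    def __rsub__(self, other):
        return _as_tensor(other).__sub__(self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return _as_tensor(other).__truediv__(self)

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def sum(self, axis=None):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                self._accumulate(np.broadcast_to(np.expand_dims(g, axis), self.data.shape))

        return Tensor(self.data.sum(axis=axis), parents=(self,), backward=bwd)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g / n, self.data.shape))
            else:
                self._accumulate(
                    np.broadcast_to(np.expand_dims(g / n, axis), self.data.shape)
                )

        return Tensor(self.data.mean(axis=axis), parents=(self,), backward=bwd)

    def item(self):
        return float(self.data)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- elementwise nonlinearities ------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accumulate(g * out * (1.0 - out))

    return Tensor(out, parents=(x,), backward=bwd)


def log(x: Tensor) -> Tensor:
    def bwd(g):
        x._accumulate(g / x.data)

    return Tensor(np.log(x.data), parents=(x,), backward=bwd)


def power(x: Tensor, p: float) -> Tensor:
    def bwd(g):
        x._accumulate(g * p * x.data ** (p - 1.0))

    return Tensor(x.data**p, parents=(x,), backward=bwd)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through-zero gradient outside [lo, hi]."""
    mask = (x.data >= lo) & (x.data <= hi)

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(np.clip(x.data, lo, hi), parents=(x,), backward=bwd)


def prelu(x: Tensor, alpha: Parameter) -> Tensor:
    """PReLU with one learnable slope per channel (channels-last layout)."""
    a = alpha.data
    pos = x.data > 0
    out = np.where(pos, x.data, a * x.data)
    reduce_axes = tuple(range(x.data.ndim - 1))

    def bwd(g):
        x._accumulate(np.where(pos, g, a * g))
        neg = np.where(pos, 0.0, x.data * g)
        alpha._accumulate(neg.sum(axis=reduce_axes))

    return Tensor(out, parents=(x, alpha), backward=bwd)


# ---- 3D convolution ------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, stride: int):
    """Unfold a padded channels-last (N,Dp,Hp,Wp,C) volume into a
    GEMM-ready (N*od*oh*ow, k^3*C) matrix. Window axes are ordered
    (kd, kh, kw, C) so both this copy and the backward scatter touch
    contiguous C-runs."""
    n, d, h, w, c = xp.shape
    od = (d - k) // stride + 1
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    sn, sd, sh, sw_, sc = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, od, oh, ow, k, k, k, c),
        strides=(sn, sd * stride, sh * stride, sw_ * stride, sd, sh, sw_, sc),
    )
    col = np.ascontiguousarray(view)
    return col.reshape(n * od * oh * ow, k**3 * c), (od, oh, ow)


def conv3d(x: Tensor, w: Parameter, b: Parameter | None, stride: int = 1) -> Tensor:
    """'Same'-style 3D convolution, channels-last (N,D,H,W,C) activations
    with (F,C,k,k,k) weights: kernel k, padding (k-1)//2, given stride.

    For stride 2 the output edge is ceil(E/2) for even E. Implemented as
    im2col + one GEMM so the heavy lifting stays in BLAS.
    """
    k = w.data.shape[2]
    f, c = w.data.shape[:2]
    pad = (k - 1) // 2
    xp = x.data
    if pad:
        xp = np.pad(xp, ((0, 0),) + ((pad, pad),) * 3 + ((0, 0),))
    col, (od, oh, ow) = _im2col(xp, k, stride)
    # weight flattened in (kd, kh, kw, C) order to match the unfold layout
    wmat = w.data.transpose(0, 2, 3, 4, 1).reshape(f, k**3 * c).T
    out2 = col @ wmat
    if b is not None:
        out2 = out2 + b.data
    n = x.data.shape[0]
    out = out2.reshape(n, od, oh, ow, f)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g2 = g.reshape(n * od * oh * ow, f)
        if b is not None:
            b._accumulate(g2.sum(axis=0))
        dw = (col.T @ g2).T.reshape(f, k, k, k, c)
        w._accumulate(dw.transpose(0, 4, 1, 2, 3))
        dcol = (g2 @ wmat.T).reshape(n, od, oh, ow, k, k, k, c)
        dxp = np.zeros_like(xp)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    sl = (
                        slice(None),
                        slice(kd, kd + stride * od, stride),
                        slice(kh, kh + stride * oh, stride),
                        slice(kw, kw + stride * ow, stride),
                        slice(None),
                    )
                    dxp[sl] += dcol[:, :, :, :, kd, kh, kw, :]
        if pad:
            dxp = dxp[:, pad:-pad, pad:-pad, pad:-pad, :]
        x._accumulate(dxp)

    return Tensor(out, parents=parents, backward=bwd)


# ---- normalization, resampling, concat -----------------------------------


def instance_norm(x: Tensor, gamma: Parameter, beta: Parameter, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) over its spatial voxels, then apply
    a per-channel affine. Channels-last layout."""
    axes = tuple(range(1, x.data.ndim - 1))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data
    m = np.prod([x.data.shape[a] for a in axes])

    def bwd(g):
        beta._accumulate(g.sum(axis=(0,) + axes))
        gamma._accumulate((g * xhat).sum(axis=(0,) + axes))
        gx = g * gamma.data
        # standard batch/instance-norm backward over the spatial axes
        dxhat_sum = gx.sum(axis=axes, keepdims=True)
        dxhat_x_sum = (gx * xhat).sum(axis=axes, keepdims=True)
        x._accumulate(inv * (gx - dxhat_sum / m - xhat * dxhat_x_sum / m))

    return Tensor(out, parents=(x, gamma, beta), backward=bwd)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out = x.data
    for ax in (1, 2, 3):
        out = np.repeat(out, factor, axis=ax)

    def bwd(g):
        n, d, h, w, c = x.data.shape
        g = g.reshape(n, d, factor, h, factor, w, factor, c)
        x._accumulate(g.sum(axis=(2, 4, 6)))

    return Tensor(out, parents=(x,), backward=bwd)


def reshape(x: Tensor, shape) -> Tensor:
    def bwd(g):
        x._accumulate(g.reshape(x.data.shape))

    return Tensor(x.data.reshape(shape), parents=(x,), backward=bwd)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the trailing (channel) axis."""
    ca = a.data.shape[-1]

    def bwd(g):
        a._accumulate(g[..., :ca])
        b._accumulate(g[..., ca:])

    return Tensor(
        np.concatenate([a.data, b.data], axis=-1), parents=(a, b), backward=bwd
    )


def moveaxis(x: Tensor, src: int, dst: int) -> Tensor:
    def bwd(g):
        x._accumulate(np.moveaxis(g, dst, src))

    return Tensor(np.moveaxis(x.data, src, dst), parents=(x,), backward=bwd)


# ---- optimizer -----------------------------------------------------------


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=5e-5, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
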