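"""Minimal reverse-mode autodiff engine for convolutional segmentation networks.

Everything runs on numpy float32 arrays laid out as (batch, height, width,
channels).  Directional ("factorized") convolutions are the workhorse: a
``k x 1`` or ``1 x k`` kernel is evaluated as ``k`` shifted GEMMs, which keeps
all heavy lifting inside BLAS and makes CPU training of small encoder-decoder
models practical.  The engine is deliberately small: only the operations the
segmentation blocks need are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv_spatial",
    "conv2d",
    "relu",
    "add",
    "concat",
    "maxpool",
    "upsample",
    "sigmoid",
    "bce_with_logits",
    "dice_loss",
    "Adam",
    "he_uniform",
]


class Tensor:
    """A node in the computation graph.

    ``data`` is a numpy array; ``grad`` is accumulated during :meth:`backward`.
    Non-leaf tensors carry a ``_backward`` closure and references to their
    parent nodes so the tape can be replayed in reverse topological order.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    @property
    def size(self):
        return int(self.data.size)


def he_uniform(rng, shape, fan_in):
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._parents or p._backward for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def conv_spatial(x, w, b, axis):
    """Same-padded 1-D convolution along a spatial axis of a (B,H,W,C) tensor.

    ``w`` has shape (k, cin, cout); ``axis`` is 1 for a kx1 kernel (height)
    or 2 for a 1xk kernel (width).  Implemented as k shifted matrix products.
    """
    k, cin, cout = w.shape
    if x.data.shape[-1] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[-1]}, kernel expects {cin}"
        )
    if axis not in (1, 2):
        raise ValueError("axis must be 1 (height) or 2 (width)")
    pad = k // 2
    B, H, W, _ = x.data.shape
    n = x.data.shape[axis]
    if k == 1:
        xcol = x.data.reshape(-1, cin)
    else:
        padding = [(0, 0)] * 4
        padding[axis] = (pad, pad)
        xp = np.pad(x.data, padding)
        # im2col: windows of length k along the chosen axis, flattened to
        # (B*H*W, k*cin) so the convolution is one GEMM.
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=axis)
        xcol = np.ascontiguousarray(np.moveaxis(win, -1, 3)).reshape(-1, k * cin)
    wm = w.data.reshape(k * cin, cout)
    out = xcol.dot(wm) + b.data
    out = out.reshape(B, H, W, cout)

    def backward(g):
        gm = g.reshape(-1, cout)
        if b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if w.requires_grad:
            w._accumulate(xcol.T.dot(gm).reshape(k, cin, cout))
        if x.requires_grad or x._parents:
            gcol = gm.dot(wm.T)  # (BHW, k*cin)
            if k == 1:
                x._accumulate(gcol.reshape(B, H, W, cin))
            else:
                gcol = gcol.reshape(B, H, W, k, cin)
                shape = list(x.data.shape)
                shape[axis] += 2 * pad
                gxp = np.zeros(shape, dtype=np.float32)
                for t in range(k):
                    sl = [slice(None)] * 4
                    sl[axis] = slice(t, t + n)
                    gxp[tuple(sl)] += gcol[:, :, :, t, :]
                sl = [slice(None)] * 4
                sl[axis] = slice(pad, pad + n)
                x._accumulate(gxp[tuple(sl)])

    return _make(out, (x, w, b), backward)


def conv2d(x, w, b):
    """Same-padded 2-D convolution; ``w`` has shape (kh, kw, cin, cout).

    Evaluated as kh*kw shifted GEMMs, like :func:`conv_spatial`.
    """
    kh, kw, cin, cout = w.shape
    if x.data.shape[-1] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[-1]}, kernel expects {cin}"
        )
    ph, pw = kh // 2, kw // 2
    B, H, W, _ = x.data.shape
    if kh == kw == 1:
        xcol = x.data.reshape(-1, cin)
    else:
        xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        # (B,H,W,C,kh,kw) -> (B,H,W,kh,kw,C) flattened to one GEMM operand
        xcol = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            -1, kh * kw * cin
        )
    wm = w.data.reshape(kh * kw * cin, cout)
    out = (xcol.dot(wm) + b.data).reshape(B, H, W, cout)

    def backward(g):
        gm = g.reshape(-1, cout)
        if b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if w.requires_grad:
            w._accumulate(xcol.T.dot(gm).reshape(kh, kw, cin, cout))
        if x.requires_grad or x._parents:
            gcol = gm.dot(wm.T)
            if kh == kw == 1:
                x._accumulate(gcol.reshape(B, H, W, cin))
            else:
                gcol = gcol.reshape(B, H, W, kh, kw, cin)
                gxp = np.zeros(
                    (B, H + 2 * ph, W + 2 * pw, cin), dtype=np.float32
                )
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, i : i + H, j : j + W, :] += gcol[:, :, :, i, j, :]
                x._accumulate(gxp[:, ph : ph + H, pw : pw + W, :])

    return _make(out, (x, w, b), backward)


def relu(x):
    mask = x.data > 0
    out = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        x._accumulate(g * mask)

    return _make(out, (x,), backward)


def add(a, b):
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in add: {a.data.shape} vs {b.data.shape}")
    out = a.data + b.data

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return _make(out, (a, b), backward)


def concat(tensors, axis=-1):
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(gpart)

    return _make(out, tuple(tensors), backward)


def maxpool(x, k):
    """Max pooling with a k x k window and stride k (window == stride)."""
    B, H, W, C = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims {(H, W)} not divisible by pool size {k}")
    win = x.data.reshape(B, H // k, k, W // k, k, C)
    win = win.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // k, W // k, k * k, C)
    idx = win.argmax(axis=3)
    out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(g):
        gw = np.zeros((B, H // k, W // k, k * k, C), dtype=np.float32)
        np.put_along_axis(gw, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gx = gw.reshape(B, H // k, W // k, k, k, C).transpose(0, 1, 3, 2, 4, 5)
        x._accumulate(gx.reshape(B, H, W, C))

    return _make(out, (x,), backward)


def upsample(x, k=2):
    """Parameter-free nearest-neighbour upsampling by an integer factor."""
    out = x.data.repeat(k, axis=1).repeat(k, axis=2)

    def backward(g):
        B, H, W, C = x.data.shape
        gx = g.reshape(B, H, k, W, k, C).sum(axis=(2, 4))
        x._accumulate(gx)

    return _make(out, (x,), backward)


def sigmoid(x):
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    return _make(out.astype(np.float32), (x,), backward)


def bce_with_logits(z, target):
    """Mean binary cross-entropy computed stably from logits."""
    t = np.asarray(target, dtype=np.float32)
    zd = z.data
    loss = np.maximum(zd, 0) - zd * t + np.log1p(np.exp(-np.abs(zd)))
    mean = np.float32(loss.mean())

    def backward(g):
        p = 1.0 / (1.0 + np.exp(-np.clip(zd, -60, 60)))
        z._accumulate(g * (p - t) / zd.size)

    return _make(mean, (z,), backward)


def dice_loss(z, target, eps=1.0):
    """Soft Dice loss (1 - DSC) on sigmoid probabilities, from logits."""
    t = np.asarray(target, dtype=np.float32)
    p = 1.0 / (1.0 + np.exp(-np.clip(z.data, -60, 60)))
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    dsc = (2.0 * inter + eps) / denom
    loss = np.float32(1.0 - dsc)

    def backward(g):
        # d/dp of -(2*sum(pt)+eps)/denom, then chain through the sigmoid
        dp = -(2.0 * t * denom - (2.0 * inter + eps)) / (denom * denom)
        z._accumulate(g * dp * p * (1.0 - p))

    return _make(loss, (z,), backward)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
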