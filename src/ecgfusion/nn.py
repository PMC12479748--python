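"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists so the residual block, the bidirectional RNN and the
spectrogram classifier can be written directly from their defining
equations, trained with decoupled-weight-decay Adam, and differentiated
for Grad-CAM — all in float64 for bit-reproducible runs on one CPU.
Only the primitives those models need are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "matmul", "tanh", "relu", "exp", "log",
    "concat", "reshape", "transpose", "tsum", "tmax_const", "getitem",
    "conv1d", "conv2d", "maxpool1d", "maxpool2d", "avgpool2d",
    "log_softmax", "softmax", "cross_entropy", "BatchNorm", "Linear",
    "Conv1d", "Conv2d", "AdamW", "he_normal",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, seed=None):
        """Backpropagate from this node (scalar unless a seed is given)."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed needs a scalar output")
            seed = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(seed, dtype=np.float64).reshape(self.data.shape)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to ``shape``."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _node(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  _parents=tuple(p for p in parents if p.requires_grad),
                  _backward=backward if req else None)


# ---------------------------------------------------------------- primitives

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.data.shape)

    return _node(out_data, (a, b), bw)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.data, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.data, b.data.shape)

    return _node(out_data, (a, b), bw)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

    return _node(out_data, (a, b), bw)


def tanh(x):
    x = _wrap(x)
    out_data = np.tanh(x.data)

    def bw(g):
        if x.requires_grad:
            x.grad += g * (1.0 - out_data ** 2)

    return _node(out_data, (x,), bw)


def relu(x):
    x = _wrap(x)
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x.grad += g * mask

    return _node(x.data * mask, (x,), bw)


def exp(x):
    x = _wrap(x)
    out_data = np.exp(x.data)

    def bw(g):
        if x.requires_grad:
            x.grad += g * out_data

    return _node(out_data, (x,), bw)


def log(x):
    x = _wrap(x)

    def bw(g):
        if x.requires_grad:
            x.grad += g / x.data

    return _node(np.log(x.data), (x,), bw)


def tsum(x, axis=None, keepdims=False):
    x = _wrap(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not x.requires_grad:
            return
        if axis is None:
            x.grad += np.broadcast_to(g, x.data.shape)
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            x.grad += np.broadcast_to(gg, x.data.shape)

    return _node(out_data, (x,), bw)


def tmax_const(x, axis=None, keepdims=False):
    """Max of a tensor as a gradient-free constant (for stable softmax)."""
    return Tensor(np.asarray(x.data.max(axis=axis, keepdims=keepdims)))


def reshape(x, shape):
    x = _wrap(x)
    old = x.data.shape

    def bw(g):
        if x.requires_grad:
            x.grad += g.reshape(old)

    return _node(x.data.reshape(shape), (x,), bw)


def transpose(x, axes):
    x = _wrap(x)
    inv = np.argsort(axes)

    def bw(g):
        if x.requires_grad:
            x.grad += g.transpose(inv)

    return _node(x.data.transpose(axes), (x,), bw)


def getitem(x, idx):
    x = _wrap(x)

    def bw(g):
        if x.requires_grad:
            buf = np.zeros_like(x.data)
            np.add.at(buf, idx, g)
            x.grad += buf

    return _node(x.data[idx], (x,), bw)


def concat(tensors, axis):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, bw)


# -------------------------------------------------------------- convolutions

def conv1d(x, w, b=None, pad=0):
    """x: (N, C, L); w: (O, C, K); 'same' length when pad = K - 1 is split."""
    x, w = _wrap(x), _wrap(w)
    n, c, length = x.data.shape
    o, _, k = w.data.shape
    pl, pr = pad // 2, pad - pad // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    lout = xp.shape[2] - k + 1
    out_data = np.zeros((n, o, lout))
    for kk in range(k):
        out_data += np.einsum("ncl,oc->nol", xp[:, :, kk:kk + lout], w.data[:, :, kk])
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        out_data += b.data[None, :, None]
        parents.append(b)

    def bw(g):
        if b is not None and b.requires_grad:
            b.grad += g.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for kk in range(k):
            if w.requires_grad:
                w.grad[:, :, kk] += np.einsum("nol,ncl->oc", g, xp[:, :, kk:kk + lout])
            gxp[:, :, kk:kk + lout] += np.einsum("nol,oc->ncl", g, w.data[:, :, kk])
        if x.requires_grad:
            x.grad += gxp[:, :, pl:pl + length]

    return _node(out_data, tuple(parents), bw)


def conv2d(x, w, b=None, pad=0):
    """x: (N, C, H, W); w: (O, C, KH, KW); symmetric zero padding."""
    x, w = _wrap(x), _wrap(w)
    n, c, h, wd = x.data.shape
    o, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hout, wout = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    out_data = np.zeros((n, o, hout, wout))
    for i in range(kh):
        for j in range(kw):
            out_data += np.einsum("nchw,oc->nohw",
                                  xp[:, :, i:i + hout, j:j + wout], w.data[:, :, i, j])
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        out_data += b.data[None, :, None, None]
        parents.append(b)

    def bw(g):
        if b is not None and b.requires_grad:
            b.grad += g.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                if w.requires_grad:
                    w.grad[:, :, i, j] += np.einsum(
                        "nohw,nchw->oc", g, xp[:, :, i:i + hout, j:j + wout])
                gxp[:, :, i:i + hout, j:j + wout] += np.einsum(
                    "nohw,oc->nchw", g, w.data[:, :, i, j])
        if x.requires_grad:
            x.grad += gxp[:, :, pad:pad + h, pad:pad + wd]

    return _node(out_data, tuple(parents), bw)


def maxpool1d(x, size):
    x = _wrap(x)
    n, c, length = x.data.shape
    lout = length // size
    win = x.data[:, :, :lout * size].reshape(n, c, lout, size)
    arg = win.argmax(axis=3)
    out_data = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        buf = np.zeros((n, c, lout, size))
        np.put_along_axis(buf, arg[..., None], g[..., None], axis=3)
        x.grad[:, :, :lout * size] += buf.reshape(n, c, lout * size)

    return _node(out_data, (x,), bw)


def maxpool2d(x, size):
    x = _wrap(x)
    n, c, h, w = x.data.shape
    ho, wo = h // size, w // size
    win = x.data[:, :, :ho * size, :wo * size].reshape(n, c, ho, size, wo, size)
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, size * size)
    arg = flat.argmax(axis=4)
    out_data = np.take_along_axis(flat, arg[..., None], axis=4)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        buf = np.zeros_like(flat)
        np.put_along_axis(buf, arg[..., None], g[..., None], axis=4)
        buf = buf.reshape(n, c, ho, wo, size, size).transpose(0, 1, 2, 4, 3, 5)
        x.grad[:, :, :ho * size, :wo * size] += buf.reshape(n, c, ho * size, wo * size)

    return _node(out_data, (x,), bw)


def avgpool2d(x, size):
    x = _wrap(x)
    n, c, h, w = x.data.shape
    ho, wo = h // size, w // size
    win = x.data[:, :, :ho * size, :wo * size].reshape(n, c, ho, size, wo, size)
    out_data = win.mean(axis=(3, 5))

    def bw(g):
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, size, axis=2), size, axis=3) / (size * size)
            x.grad[:, :, :ho * size, :wo * size] += gg

    return _node(out_data, (x,), bw)


# ------------------------------------------------------------------- heads

def log_softmax(x, axis=-1):
    s = x - tmax_const(x, axis=axis, keepdims=True)
    return s - log(tsum(exp(s), axis=axis, keepdims=True))


def softmax(x, axis=-1):
    ls = log_softmax(x, axis)
    return exp(ls)


def cross_entropy(logits, labels):
    """Mean categorical cross-entropy; labels are integer class indices."""
    labels = np.asarray(labels)
    n, k = logits.data.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    ls = log_softmax(logits, axis=1)
    return mul(tsum(mul(ls, Tensor(onehot))), Tensor(-1.0 / n))


# ------------------------------------------------------------------- layers

def he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear:
    def __init__(self, rng, n_in, n_out):
        self.w = Tensor(he_normal(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x):
        return matmul(x, self.w) + self.b

    def params(self):
        return [self.w, self.b]


class Conv1d:
    def __init__(self, rng, c_in, c_out, k):
        self.k = k
        self.w = Tensor(he_normal(rng, (c_out, c_in, k), c_in * k), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return conv1d(x, self.w, self.b, pad=self.k - 1)

    def params(self):
        return [self.w, self.b]


class Conv2d:
    def __init__(self, rng, c_in, c_out, k):
        self.k = k
        self.w = Tensor(he_normal(rng, (c_out, c_in, k, k), c_in * k * k),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return conv2d(x, self.w, self.b, pad=self.k // 2)

    def params(self):
        return [self.w, self.b]


class BatchNorm:
    """Batch normalization over the channel axis of (N, C, ...) tensors.

    Training mode normalizes with batch statistics and updates running
    moments; eval mode applies the affine map from the running moments,
    which is the inference form the residual-block equation assumes.
    """

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x):
        axes = (0,) + tuple(range(2, x.data.ndim))
        bshape = (1, -1) + (1,) * (x.data.ndim - 2)
        if self.training:
            m = x.data.mean(axis=axes)
            v = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v
            count = x.data.size / x.data.shape[1]
            mean_t = mul(tsum(x, axis=axes, keepdims=True), Tensor(1.0 / count))
            centred = x - mean_t
            var_t = mul(tsum(mul(centred, centred), axis=axes, keepdims=True),
                        Tensor(1.0 / count))
            inv = exp(mul(log(var_t + Tensor(self.eps)), Tensor(-0.5)))
            xhat = mul(centred, inv)
        else:
            xhat = mul(x - Tensor(self.running_mean.reshape(bshape)),
                       Tensor(1.0 / np.sqrt(self.running_var.reshape(bshape) + self.eps)))
        return mul(xhat, reshape(self.gamma, bshape)) + reshape(self.beta, bshape)

    def params(self):
        return [self.gamma, self.beta]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-4, weight_decay=0.01,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
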