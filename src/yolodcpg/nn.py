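"""Minimal neural-network layer library on top of :mod:`yolodcpg.autograd`.

Implements exactly the layer set the detector needs — dense and depthwise
2-D convolution (im2col / windowed einsum), batch normalisation, ReLU6 and
SiLU activations, stride-1 max pooling, nearest-neighbour upsampling — plus
parameter enumeration and a multiply-accumulate (MAC) counter used for the
GFLOP profiling convention (2 x conv MACs; normalisation, activations,
pooling and resampling count as zero, i.e. the fused-model convention).
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, astensor, is_grad_enabled

# ---------------------------------------------------------------------------
# MAC counting
# ---------------------------------------------------------------------------

_mac_counter = None


@contextlib.contextmanager
def count_macs():
    """Context manager collecting conv/matmul multiply-accumulates.

    Yields a one-element list; after the block, ``counter[0]`` holds the MACs.
    """
    global _mac_counter
    prev = _mac_counter
    _mac_counter = [0]
    try:
        yield _mac_counter
    finally:
        _mac_counter = prev


def _add_macs(n: int):
    if _mac_counter is not None:
        _mac_counter[0] += int(n)


# ---------------------------------------------------------------------------
# Module base
# ---------------------------------------------------------------------------


class Module:
    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v
            elif isinstance(value, dict):
                for k, v in value.items():
                    if isinstance(v, Module):
                        yield f"{name}.{k}", v

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        seen = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state I/O -------------------------------------------------------
    def state_dict(self):
        state = {f"p:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"b:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for k, v in self.named_parameters():
            v.data = np.asarray(state[f"p:{k}"], dtype=v.data.dtype).reshape(v.data.shape)
        for k, v in self.named_buffers():
            v[...] = np.asarray(state[f"b:{k}"]).reshape(v.shape)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def parameter(shape, init="zeros", rng=None, gain=1.0) -> Tensor:
    if init == "zeros":
        data = np.zeros(shape, dtype=np.float32)
    elif init == "ones":
        data = np.ones(shape, dtype=np.float32)
    elif init == "kaiming":
        fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
        bound = gain * math.sqrt(1.0 / max(fan_in, 1))
        data = (rng or np.random.default_rng()).uniform(-bound, bound, size=shape).astype(np.float32)
    else:
        raise ValueError(init)
    t = Tensor(data)
    t.requires_grad = True
    return t


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------


def _pad_nchw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _conv2d_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int, groups: int):
    """Forward conv; returns (out, cols) where cols is reused by backward."""
    n, cin, h, wd = x.shape
    cout, cing, kh, kw = w.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    _add_macs(kh * kw * (cin // groups) * cout * ho * wo * n)
    if groups == cin and cout == cin and cing == 1:
        # depthwise: k*k shifted multiply-accumulates (no window copies)
        xp = _pad_nchw(x, pad)
        out = np.zeros((n, cin, ho, wo), dtype=x.dtype)
        for u in range(kh):
            for v in range(kw):
                out += xp[:, :, u:u + stride * ho:stride, v:v + stride * wo:stride] \
                    * w[:, 0, u, v][None, :, None, None]
        return out, None
    if groups != 1:
        raise NotImplementedError("only dense or depthwise convolution is supported")
    if kh == 1 and kw == 1 and stride == 1 and pad == 0:
        out = np.tensordot(w[:, :, 0, 0], x, axes=([1], [1])).transpose(1, 0, 2, 3)
        return np.ascontiguousarray(out), None
    xp = _pad_nchw(x, pad)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    out = (cols @ w.reshape(cout, -1).T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols


def _col2im(gcols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    g6 = gcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for u in range(k):
        for v in range(k):
            gx[:, :, u:u + stride * ho:stride, v:v + stride * wo:stride] += g6[:, :, :, :, u, v]
    return gx[:, :, pad:pad + h, pad:pad + w] if pad else gx


class Conv2d(Module):
    """2-D convolution (dense or depthwise), optionally with bias."""

    def __init__(self, cin, cout, k, stride=1, pad=None, groups=1, bias=True, rng=None):
        super().__init__()
        if groups not in (1, cin) or (groups == cin and cout != cin and groups != 1):
            if not (groups == 1 or (groups == cin and cout == cin)):
                raise ValueError("groups must be 1 (dense) or cin==cout (depthwise)")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.groups = groups
        self.weight = parameter((cout, cin // groups, k, k), "kaiming", rng=rng)
        self.bias = parameter((cout,), "zeros") if bias else None

    def forward(self, x):
        x = astensor(x)
        w = self.weight
        out_data, cols = _conv2d_raw(x.data, w.data, self.stride, self.pad, self.groups)
        parents = [x, w]
        stride, pad, groups, k = self.stride, self.pad, self.groups, self.k
        xshape = x.shape

        def bwd(g):
            g = np.ascontiguousarray(g)
            if groups == 1 and k == 1 and stride == 1 and pad == 0:
                n, cout, ho, wo = g.shape
                gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))[:, :, None, None]
                gx = np.tensordot(w.data[:, :, 0, 0].T, g, axes=([1], [1])).transpose(1, 0, 2, 3)
                return (np.ascontiguousarray(gx), gw)
            if groups == 1:
                n, cout, ho, wo = g.shape
                gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
                gw = (gmat.T @ cols).reshape(w.shape)
                gcols = gmat @ w.data.reshape(cout, -1)
                gx = _col2im(gcols, xshape, k, stride, pad)
            else:  # depthwise: mirror the shifted-accumulate forward
                n, c, ho, wo = g.shape
                xp = _pad_nchw(x.data, pad)
                gxp = np.zeros_like(xp)
                gw = np.zeros_like(w.data)
                for u in range(k):
                    for v in range(k):
                        sl = np.s_[:, :, u:u + stride * ho:stride, v:v + stride * wo:stride]
                        gw[:, 0, u, v] = (xp[sl] * g).sum(axis=(0, 2, 3))
                        gxp[sl] += g * w.data[:, 0, u, v][None, :, None, None]
                gx = gxp[:, :, pad:pad + xshape[2], pad:pad + xshape[3]] if pad else gxp
            return (gx, gw)

        out = Tensor._make(out_data, parents, bwd)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = parameter((c,), "ones")
        self.bias = parameter((c,), "zeros")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        x = astensor(x)
        if self.training and is_grad_enabled():
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / std)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class ReLU6(Module):
    def forward(self, x):
        return astensor(x).clip(0.0, 6.0)


class SiLU(Module):
    def forward(self, x):
        x = astensor(x)
        return x * x.sigmoid()


class MaxPool2d(Module):
    """Max pooling with 'same'-style padding (used by SPPF: k=5, stride=1)."""

    def __init__(self, k, stride=1, pad=None):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad

    def forward(self, x):
        x = astensor(x)
        k, s, p = self.k, self.stride, self.pad
        xp = _pad_nchw(x.data, p)
        if p:
            xp[:, :, :p, :] = -np.inf
            xp[:, :, -p:, :] = -np.inf
            xp[:, :, :, :p] = -np.inf
            xp[:, :, :, -p:] = -np.inf
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo, _, _ = win.shape
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        xshape = x.shape

        def bwd(g):
            gx = np.zeros((n, c, xshape[2] + 2 * p, xshape[3] + 2 * p), dtype=g.dtype)
            ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
            rows = ii[None, None] * s + idx // k
            colsx = jj[None, None] * s + idx % k
            nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
            np.add.at(gx, (nn_[..., None, None], cc[..., None, None], rows, colsx), g)
            return (gx[:, :, p:p + xshape[2], p:p + xshape[3]] if p else gx,)

        return Tensor._make(np.ascontiguousarray(out_data), (x,), bwd)


class Upsample2x(Module):
    """Nearest-neighbour x2 spatial upsampling."""

    def forward(self, x):
        x = astensor(x)
        out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
        n, c, h, w = x.shape

        def bwd(g):
            return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

        return Tensor._make(out, (x,), bwd)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
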