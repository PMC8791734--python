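"""Minimal reverse-mode automatic differentiation and neural-net layers on numpy.

This is the numerical substrate for the two small convolutional networks in the
package: the ResNet-7 slice classifier used by Mean-Teacher curation and the
depthwise-separable U-Net used for segmentation.  It provides a tape-based
:class:`Tensor`, the handful of primitives those architectures need (dense and
depthwise im2col convolutions, batch norm, 3x3/stride-2 max pooling, x2 bilinear
upsampling, concatenation, softmax/sigmoid), and an Adam optimizer.  Everything
is float64 and single-threaded; gradients are checked against finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "Linear",
    "MaxPool2d3s2",
    "Adam",
    "concat",
    "upsample_bilinear2x",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph machinery ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() only on scalar outputs")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw(g):
            self._accum(g / self.data)

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def bw(g):
            self._accum(g * e)

        out._backward = bw
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = Tensor(ls, _prev=(self,))
        s = np.exp(ls)

        def bw(g):
            self._accum(g - s * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only in the interior."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accum(g * mask)

        out._backward = bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def bw(g):
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out._backward = bw
        return out

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, idx, g)
            self._accum(dx)

        out._backward = bw
        return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution primitives (stride 1, square kernel, "same" padding for k=3)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Dense 2D convolution, stride 1.  x: (N,C,H,W); w: (O,C,k,k); b: (O,).

    Implemented as k*k shifted matmuls rather than one big im2col so the tape
    retains only the padded input (keeps peak memory proportional to the
    activations, not 9x them).
    """
    k = w.data.shape[-1]
    N, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho, Wo = H + 2 * pad - k + 1, W + 2 * pad - k + 1
    out_data = np.empty((N, w.data.shape[0], Ho, Wo))
    out_data[:] = b.data[None, :, None, None]
    for i in range(k):
        for j in range(k):
            out_data += np.einsum(
                "oc,nchw->nohw", w.data[:, :, i, j], xp[:, :, i : i + Ho, j : j + Wo],
                optimize=True,
            )
    out = Tensor(out_data, _prev=(x, w, b))

    def bw(g):
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i : i + Ho, j : j + Wo]
                dw[:, :, i, j] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i : i + Ho, j : j + Wo] += np.einsum(
                    "oc,nohw->nchw", w.data[:, :, i, j], g, optimize=True
                )
        w._accum(dw)
        b._accum(g.sum(axis=(0, 2, 3)))
        x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = bw
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Depthwise 2D convolution, stride 1.  w: (C,k,k); one filter per channel."""
    k = w.data.shape[-1]
    N, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho, Wo = H + 2 * pad - k + 1, W + 2 * pad - k + 1
    out_data = np.empty((N, C, Ho, Wo))
    out_data[:] = b.data[None, :, None, None]
    for i in range(k):
        for j in range(k):
            out_data += w.data[None, :, i, j, None, None] * xp[
                :, :, i : i + Ho, j : j + Wo
            ]
    out = Tensor(out_data, _prev=(x, w, b))

    def bw(g):
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i : i + Ho, j : j + Wo]
                dw[:, i, j] = (g * sl).sum(axis=(0, 2, 3))
                dxp[:, :, i : i + Ho, j : j + Wo] += w.data[None, :, i, j, None, None] * g
        w._accum(dw)
        b._accum(g.sum(axis=(0, 2, 3)))
        x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = bw
    return out


def maxpool2d_3s2(x: Tensor) -> Tensor:
    """3x3 max pooling with stride 2 and padding 1 (halves H and W)."""
    N, C, H, W = x.data.shape
    xp = np.full((N, C, H + 2, W + 2), -np.inf)
    xp[:, :, 1 : 1 + H, 1 : 1 + W] = x.data
    Ho, Wo = (H - 1) // 2 + 1, (W - 1) // 2 + 1
    patches = np.empty((N, C, 9, Ho, Wo))
    for i in range(3):
        for j in range(3):
            patches[:, :, 3 * i + j] = xp[
                :, :, i : i + 2 * (Ho - 1) + 1 : 2, j : j + 2 * (Wo - 1) + 1 : 2
            ]
    arg = patches.argmax(axis=2)
    out = Tensor(np.take_along_axis(patches, arg[:, :, None], axis=2)[:, :, 0], _prev=(x,))

    def bw(g):
        dxp = np.zeros((N, C, H + 2, W + 2))
        for i in range(3):
            for j in range(3):
                m = arg == (3 * i + j)
                dxp[:, :, i : i + 2 * (Ho - 1) + 1 : 2, j : j + 2 * (Wo - 1) + 1 : 2] += (
                    m * g
                )
        x._accum(dxp[:, :, 1 : 1 + H, 1 : 1 + W])

    out._backward = bw
    return out


def _interp_weights(n_out: int, n_in: int):
    src = np.clip((np.arange(n_out) + 0.5) / 2.0 - 0.5, 0.0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, 1.0 - w1, w1


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling on the trailing two axes (align_corners=False)."""
    N, C, H, W = x.data.shape
    ri0, ri1, rw0, rw1 = _interp_weights(2 * H, H)
    ci0, ci1, cw0, cw1 = _interp_weights(2 * W, W)
    tmp = x.data[:, :, ri0, :] * rw0[None, None, :, None] + x.data[:, :, ri1, :] * rw1[
        None, None, :, None
    ]
    out_data = tmp[:, :, :, ci0] * cw0[None, None, None, :] + tmp[:, :, :, ci1] * cw1[
        None, None, None, :
    ]
    out = Tensor(out_data, _prev=(x,))

    def bw(g):
        dtmp = np.zeros((N, C, 2 * H, W))
        np.add.at(dtmp, (slice(None), slice(None), slice(None), ci0), g * cw0)
        np.add.at(dtmp, (slice(None), slice(None), slice(None), ci1), g * cw1)
        dx = np.zeros((N, C, H, W))
        np.add.at(
            dx, (slice(None), slice(None), ri0), dtmp * rw0[None, None, :, None]
        )
        np.add.at(
            dx, (slice(None), slice(None), ri1), dtmp * rw1[None, None, :, None]
        )
        x._accum(dx)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter traversal, train/eval mode, flat state dict."""

    def parameters(self) -> list:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _modules(self):
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def set_training(self, flag: bool) -> None:
        if hasattr(self, "training"):
            self.training = flag
        for m in self._modules():
            m.set_training(flag)

    def buffers(self) -> list:
        """Non-trainable arrays (batch-norm running stats)."""
        bufs = []
        for v in vars(self).values():
            if isinstance(v, Module):
                bufs.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        bufs.extend(item.buffers())
        if isinstance(self, BatchNorm2d):
            bufs.extend([self.running_mean, self.running_var])
        return bufs

    def state_arrays(self) -> list:
        return [p.data for p in self.parameters()] + self.buffers()

    def load_state_arrays(self, arrays: list) -> None:
        own = self.parameters()
        nb = self.buffers()
        if len(arrays) != len(own) + len(nb):
            raise ValueError("state size mismatch")
        for p, a in zip(own, arrays[: len(own)]):
            p.data[...] = a
        for b, a in zip(nb, arrays[len(own) :]):
            b[...] = a


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.pad = k // 2
        self.w = _he_init(rng, (cout, cin, k, k), cin * k * k)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, ch: int, k: int, rng: np.random.Generator):
        self.pad = k // 2
        self.w = _he_init(rng, (ch, k, k), k * k)
        self.b = Tensor(np.zeros(ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.w, self.b, self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (
                1 - self.momentum
            ) * self.running_mean + self.momentum * mu
            self.running_var = (
                1 - self.momentum
            ) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
        out_data = (
            self.gamma.data[None, :, None, None] * xhat
            + self.beta.data[None, :, None, None]
        )
        out = Tensor(out_data, _prev=(x, self.gamma, self.beta))
        training = self.training

        def bw(g):
            self.gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            self.beta._accum(g.sum(axis=(0, 2, 3)))
            gam = self.gamma.data[None, :, None, None]
            if not training:
                x._accum(g * gam / std[None, :, None, None])
                return
            m = g.shape[0] * g.shape[2] * g.shape[3]
            dxhat = g * gam
            sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (
                dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m
            ) / std[None, :, None, None]
            x._accum(dx)

        out._backward = bw
        return out


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = _he_init(rng, (cin, cout), cin)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class MaxPool2d3s2(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2d_3s2(x)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
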