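"""Minimal feed-forward neural-network layers with explicit backprop.

All spatial layers use NCHW float arrays. Each layer caches what its
backward pass needs during ``forward``; ``backward`` consumes the cache,
accumulates parameter gradients and returns the gradient with respect to
its input. Everything is deterministic: parameter initialisation is driven
by an explicit ``numpy.random.Generator`` and no layer draws randomness at
forward time.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: registers sub-modules/parameters on attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        """Update a registered buffer in place of re-registration."""
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -------------------------------------------------------
    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self):
        for m in self.modules():
            yield from m._params.values()

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- (de)serialisation ----------------------------------------------
    def state_dict(self) -> dict:
        state = {f"param.{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": np.asarray(v).copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        for k, p in self.named_parameters():
            p.data[...] = state[f"param.{k}"]
        buf_state = {k[len("buffer."):]: v for k, v in state.items() if k.startswith("buffer.")}

        def _assign(mod: Module, prefix: str):
            for name in list(mod._buffers):
                key = prefix + name
                if key in buf_state:
                    mod._set_buffer(name, np.asarray(buf_state[key]).copy())
            for mname, sub in mod._modules.items():
                _assign(sub, prefix + mname + ".")

        _assign(self, "")

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col + matmul.

    Supports rectangular kernels (e.g. 1x3 / 3x1 factorised convolutions),
    arbitrary stride and zero padding. Kaiming-normal initialisation.
    """

    def __init__(self, cin, cout, kernel, stride=1, padding=0, rng=None, bias=True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(padding)
        rng = rng or np.random.default_rng(0)
        fan_in = cin * self.kh * self.kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, self.kh, self.kw))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        ho = (h + 2 * self.ph - self.kh) // self.sh + 1
        wo = (w + 2 * self.pw - self.kw) // self.sw + 1
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, :: self.sh, :: self.sw]  # n,c,ho,wo,kh,kw
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, -1)
        wmat = self.weight.data.reshape(self.cout, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return out.transpose(0, 2, 1).reshape(n, self.cout, ho, wo)

    def backward(self, grad):
        cols, xshape, xpshape, ho, wo = self._cache
        n = xshape[0]
        g = grad.reshape(n, self.cout, ho * wo).transpose(0, 2, 1)  # n, L, cout
        self.weight.grad += np.einsum("nlo,nlk->ok", g, cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 1))
        dcols = g @ self.weight.data.reshape(self.cout, -1)  # n, L, cin*kh*kw
        dcols = dcols.reshape(n, ho, wo, self.cin, self.kh, self.kw)
        dxp = np.zeros(xpshape)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + self.sh * ho : self.sh, j : j + self.sw * wo : self.sw] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if self.ph or self.pw:
            dxp = dxp[
                :,
                :,
                self.ph : dxp.shape[2] - self.ph or None,
                self.pw : dxp.shape[3] - self.pw or None,
            ]
        return dxp


class Linear(Module):
    def __init__(self, nin, nout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nout, nin)))
        self.bias = Parameter(np.zeros(nout))
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class ChannelSoftmax(Module):
    """Softmax across the channel axis of an NCHW tensor."""

    def forward(self, x):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=1, keepdims=True))


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self._set_buffer(
                "running_mean", (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self._set_buffer(
                "running_var", (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad):
        xhat, invstd, shape = self._cache
        n_elem = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * invstd[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / n_elem) * (n_elem * g - gsum - xhat * gx_sum)


class MaxPool2d(Module):
    """Non-overlapping 2x2 max pooling; ties resolve to the first window slot."""

    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        k = self.k
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError("spatial size must be divisible by pool size")
        v = x.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // k, w // k, k * k)
        idx = v.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, (n, c, h, w) = self._cache
        k = self.k
        dv = np.zeros((n, c, h // k, w // k, k * k))
        np.put_along_axis(dv, idx[..., None], grad[..., None], axis=-1)
        dv = dv.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(n, c, h, w)


class AvgPool2d(Module):
    """kxk average pooling, stride 1, zero padding (count includes padding)."""

    def __init__(self, k=3, padding=1):
        super().__init__()
        self.k, self.pad = k, padding

    def forward(self, x):
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        self._shape = x.shape
        self._xpshape = xp.shape
        return win.mean(axis=(-2, -1))

    def backward(self, grad):
        k, p = self.k, self.pad
        dxp = np.zeros(self._xpshape)
        ho, wo = grad.shape[2], grad.shape[3]
        g = grad / (k * k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho, j : j + wo] += g
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Module):
    """NCHW -> NC mean over the spatial axes."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w) + np.zeros(
            self._shape
        )


def _interp_coords(n_out, n_in):
    """Bilinear source indices/weights (align_corners=False convention)."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = src - i0
    return i0, i1, w


class BilinearUpsample(Module):
    """Resize NCHW to a target spatial size by bilinear interpolation."""

    def __init__(self, size=None, scale=None):
        super().__init__()
        if (size is None) == (scale is None):
            raise ValueError("specify exactly one of size / scale")
        self.size = _pair(size) if size is not None else None
        self.scale = scale

    def _target(self, h, w):
        if self.size is not None:
            return self.size
        return int(h * self.scale), int(w * self.scale)

    def forward(self, x):
        n, c, h, w = x.shape
        ho, wo = self._target(h, w)
        r0, r1, wr = _interp_coords(ho, h)
        c0, c1, wc = _interp_coords(wo, w)
        tmp = x[:, :, r0, :] * (1 - wr)[None, None, :, None] + x[:, :, r1, :] * wr[None, None, :, None]
        out = tmp[:, :, :, c0] * (1 - wc) + tmp[:, :, :, c1] * wc
        self._cache = (x.shape, (r0, r1, wr), (c0, c1, wc), tmp.shape)
        return out

    def backward(self, grad):
        xshape, (r0, r1, wr), (c0, c1, wc), tmpshape = self._cache
        dtmp = np.zeros(tmpshape)
        np.add.at(dtmp, (Ellipsis, c0), grad * (1 - wc))
        np.add.at(dtmp, (Ellipsis, c1), grad * wc)
        dx = np.zeros(xshape)
        # scatter along the row axis: move it last for np.add.at
        dtmp_t = dtmp.transpose(0, 1, 3, 2)
        dx_t = np.zeros((xshape[0], xshape[1], xshape[3], xshape[2]))
        np.add.at(dx_t, (Ellipsis, r0), dtmp_t * (1 - wr))
        np.add.at(dx_t, (Ellipsis, r1), dtmp_t * wr)
        dx = dx_t.transpose(0, 1, 3, 2)
        return dx


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            setattr(self, f"l{i}", l)

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Residual(Module):
    """y = relu(x + body(x)); body must preserve shape."""

    def __init__(self, body: Module):
        super().__init__()
        self.body = body

    def forward(self, x):
        s = x + self.body(x)
        self._mask = s > 0
        return s * self._mask

    def backward(self, grad):
        g = grad * self._mask
        return g + self.body.backward(g)


class Concat(Module):
    """Channel-axis concatenation of a fixed number of inputs."""

    def forward(self, xs):
        self._splits = np.cumsum([x.shape[1] for x in xs])[:-1]
        return np.concatenate(xs, axis=1)

    def backward(self, grad):
        return np.split(grad, self._splits, axis=1)
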