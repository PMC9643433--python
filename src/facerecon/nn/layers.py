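"""Minimal numpy layer stack with manual backpropagation.

Layers cache whatever the immediately preceding ``forward`` produced, so the
calling pattern is strictly forward-then-backward per pass.  Parameter
gradients *accumulate* across backward calls; call ``zero_grad`` on the
container before each optimization step.  All arrays are float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Dropout",
    "Sequential",
]


def im2col(x, k, stride, pad):
    """Unfold k x k patches of ``x`` (N,C,H,W) into (N, C*k*k, out_h*out_w)."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), (oh, ow)


def col2im(cols, x_shape, k, stride, pad):
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image grid."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def params_and_grads(self):
        """Yield (name, value-array, grad-array, weight_decay) tuples."""
        return ()

    def zero_grad(self):
        for _, _, g, _ in self.params_and_grads():
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, weight_decay=0.0, init_std=None):
        std = init_std if init_std is not None else np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.weight_decay = weight_decay

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    def params_and_grads(self):
        yield ("W", self.W, self.dW, self.weight_decay)
        yield ("b", self.b, self.db, 0.0)


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k=3, stride=1, pad=1, rng=None, weight_decay=0.0, init_std=None):
        std = init_std if init_std is not None else np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, std, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self.weight_decay = weight_decay

    def forward(self, x, train=False):
        self._x_shape = x.shape
        self._cols, (oh, ow) = im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("ok,nkl->nol", self.W, self._cols)
        out += self.b[None, :, None]
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout):
        n = dout.shape[0]
        dflat = dout.reshape(n, dout.shape[1], -1)
        self.dW += np.einsum("nol,nkl->ok", dflat, self._cols)
        self.db += dflat.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", self.W, dflat)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)

    def params_and_grads(self):
        yield ("W", self.W, self.dW, self.weight_decay)
        yield ("b", self.b, self.db, 0.0)


class ConvTranspose2d(Layer):
    """Transposed convolution (adjoint of a strided conv); k=4, s=2, p=1 doubles H and W."""

    def __init__(self, c_in, c_out, k=4, stride=2, pad=1, rng=None, init_std=0.02):
        self.W = rng.normal(0.0, init_std, size=(c_in, c_out * k * k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_out = c_out

    def out_size(self, h):
        return self.stride * (h - 1) + self.k - 2 * self.pad

    def forward(self, x, train=False):
        n, c_in, h, w = x.shape
        self._x_flat = x.reshape(n, c_in, h * w)
        oh, ow = self.out_size(h), self.out_size(w)
        self._out_shape = (n, self.c_out, oh, ow)
        cols = np.einsum("ik,nil->nkl", self.W, self._x_flat)
        out = col2im(cols, self._out_shape, self.k, self.stride, self.pad)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        dcols, _ = im2col(dout, self.k, self.stride, self.pad)
        self.dW += np.einsum("nil,nkl->ik", self._x_flat, dcols)
        self.db += dout.sum(axis=(0, 2, 3))
        dx_flat = np.einsum("ik,nkl->nil", self.W, dcols)
        n, c_in, _ = dx_flat.shape
        h = int(np.sqrt(dx_flat.shape[2]))
        return dx_flat.reshape(n, c_in, h, -1)

    def params_and_grads(self):
        yield ("W", self.W, self.dW, 0.0)
        yield ("b", self.b, self.db, 0.0)


class MaxPool2d(Layer):
    def __init__(self, size=2):
        self.size = size

    def forward(self, x, train=False):
        s = self.size
        n, c, h, w = x.shape
        self._x_shape = x.shape
        xr = x.reshape(n, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // s, w // s, s * s)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        s = self.size
        n, c, h, w = self._x_shape
        dxr = np.zeros((n, c, h // s, w // s, s * s))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout):
        return dout * (1.0 - self._out**2)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape  # per-sample shape, batch dim excluded

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if train and self.p > 0:
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        if self._mask is not None:
            return dout * self._mask
        return dout


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params_and_grads(self):
        for i, layer in enumerate(self.layers):
            for name, v, g, wd in layer.params_and_grads():
                yield (f"{i}.{name}", v, g, wd)

    def n_params(self):
        return sum(v.size for _, v, _, _ in self.params_and_grads())
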