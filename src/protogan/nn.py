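"""Neural-network layers and optimizers on the autodiff engine.

Layout conventions follow DCGAN practice: 5x5 kernels with stride 2 and
'same'-style padding, so every layer exactly halves (or, transposed,
doubles) the spatial size.  Images are NHWC, which keeps every reshape
around the convolution matmuls a zero-copy view.  The im2col step is a
pure column gather (each patch entry reads exactly one pixel), realized
by a cached :class:`~.autodiff.ColIndexPlan`, so derivatives of any
order - including the gradient-penalty double backward - stay exact.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import ColIndexPlan, Tensor

DTYPE = np.float32

# ---------------------------------------------------------------------------
# im2col gather plans (NHWC)


_PLAN_CACHE: dict = {}


def conv_plan(H, W, C, k, stride):
    """Gather plan for a kxk/stride 'same' convolution over (H, W, C).

    Output columns are ordered ``(oh, ow, kh, kw, c)``; padding taps point
    at the plan's zero sentinel.  Returns ``(plan, OH, OW)``.
    """
    key = (H, W, C, k, stride)
    hit = _PLAN_CACHE.get(key)
    if hit is not None:
        return hit
    pt, _ = _same_pads(H, k, stride)
    pl, _ = _same_pads(W, k, stride)
    OH = -(-H // stride)
    OW = -(-W // stride)
    oh, ow, kh, kw, c = np.meshgrid(
        np.arange(OH), np.arange(OW), np.arange(k), np.arange(k), np.arange(C),
        indexing="ij",
    )
    ih = oh * stride - pt + kh
    iw = ow * stride - pl + kw
    valid = (ih >= 0) & (ih < H) & (iw >= 0) & (iw < W)
    idx = np.where(valid, ih * W * C + iw * C + c, H * W * C)
    hit = (ColIndexPlan(idx.ravel(), H * W * C), OH, OW)
    _PLAN_CACHE[key] = hit
    return hit


def _same_pads(size: int, k: int, stride: int):
    """TensorFlow-style SAME padding split (begin, end)."""
    total = max(k - stride, 0) if size % stride == 0 else max(k - size % stride, 0)
    return total // 2, total - total // 2


# ---------------------------------------------------------------------------
# modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: parameter discovery plus train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self, prefix=""):
        """Flat name -> ndarray mapping of parameters and buffers."""
        out = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[prefix + name] = v.data
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                out[prefix + name] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix + name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{prefix}{name}.{i}."))
        return out

    def load_state_arrays(self, state, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                v.data = np.asarray(state[prefix + name], dtype=DTYPE)
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                setattr(self, name, np.asarray(state[prefix + name]))
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{prefix}{name}.{i}.")

    def __call__(self, x):
        return self.forward(x)


class Dense(Module):
    def __init__(self, n_in, n_out, rng, w_sd=0.02):
        super().__init__()
        self.W = Parameter(rng.normal(0.0, w_sd, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x):
        return ad.matmul(x, self.W) + self.b


class Conv2d(Module):
    """5x5/stride-2 'same' convolution halving the spatial size (NHWC)."""

    def __init__(self, c_in, c_out, rng, k=5, stride=2, w_sd=0.02):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.W = Parameter(rng.normal(0.0, w_sd, size=(k * k * c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))

    def forward(self, x):
        B, H, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        plan, OH, OW = conv_plan(H, W, C, self.k, self.stride)
        cols = ad.gather_cols(x.reshape((B, H * W * C)), plan)
        y = ad.matmul(cols.reshape((B * OH * OW, self.k * self.k * C)), self.W)
        return (y + self.b).reshape((B, OH, OW, self.c_out))


class ConvTranspose2d(Module):
    """Adjoint of the stride-2 'same' convolution; doubles spatial size."""

    def __init__(self, c_in, c_out, rng, k=5, stride=2, w_sd=0.02):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.W = Parameter(rng.normal(0.0, w_sd, size=(c_in, k * k * c_out)))
        self.b = Parameter(np.zeros(c_out))

    def forward(self, x):
        B, H, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        OH, OW = H * self.stride, W * self.stride
        plan, oh, ow = conv_plan(OH, OW, self.c_out, self.k, self.stride)
        assert (oh, ow) == (H, W)
        cols = ad.matmul(x.reshape((B * H * W, C)), self.W)
        cols = cols.reshape((B, H * W * self.k * self.k * self.c_out))
        y = ad.scatter_cols(cols, plan).reshape((B, OH, OW, self.c_out))
        return y + self.b


class BatchNorm2d(Module):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        if self.training:
            m = x.mean(axis=(0, 1, 2), keepdims=True)
            d = x - m
            v = (d * d).mean(axis=(0, 1, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * m.data.reshape(-1)
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * v.data.reshape(-1)
            ).astype(DTYPE)
            xhat = d / ad.sqrt(v + self.eps)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x):
        return ad.tanh(x)


class Flatten(Module):
    def forward(self, x):
        return x.reshape((x.shape[0], -1))


class GlobalAvgPool(Module):
    def forward(self, x):
        return x.mean(axis=(1, 2))


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# gradient plumbing and optimizers


def backward(loss: Tensor, params, create_graph: bool = False):
    """Populate ``p.grad`` (ndarray) for every parameter."""
    grads = ad.grad(loss, params, create_graph=create_graph)
    for p, g in zip(params, grads):
        p.grad = None if g is None else np.asarray(g.data, dtype=p.dtype)
    return grads


class Adam:
    def __init__(self, params, lr, betas=(0.5, 0.9), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params, lr):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is None:
                continue
            p.data = p.data - self.lr * p.grad
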