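"""Layers and optimizer built on :mod:`comodseg.autograd`."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery (torch-like, minimal)."""

    def parameters(self):
        params = []
        seen = set()
        for value in vars(self).values():
            self._collect(value, params, seen)
        return params

    @staticmethod
    def _collect(value, params, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            for p in value.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        elif isinstance(value, (list, tuple)):
            for item in value:
                Module._collect(item, params, seen)
        elif isinstance(value, dict):
            for item in value.values():
                Module._collect(item, params, seen)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint/config mismatch: {len(state)} arrays for {len(params)} parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=ag.dtype())
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint/config mismatch: parameter {i} shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


class Conv3d(Module):
    def __init__(self, in_channels, out_channels, kernel_size=3, stride=1,
                 padding=None, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        k = int(kernel_size)
        if padding is None:
            padding = k // 2
        fan_in = in_channels * k ** 3
        scale = np.sqrt(2.0 / fan_in)  # He init for leaky-ish activations
        self.weight = Parameter(rng.normal(0.0, scale, (out_channels, in_channels, k, k, k)))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = int(stride)
        self.padding = int(padding)

    def forward(self, x):
        return ag.conv3d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.eps = float(eps)

    def forward(self, x):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3, 4), keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class ConvBlock(Module):
    """conv -> instance norm -> leaky ReLU."""

    def __init__(self, in_channels, out_channels, stride=1, rng=None, slope=0.1):
        self.conv = Conv3d(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.norm = InstanceNorm3d(out_channels)
        self.slope = slope

    def forward(self, x):
        return ag.leaky_relu(self.norm(self.conv(x)), self.slope)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
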