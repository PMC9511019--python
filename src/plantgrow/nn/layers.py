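"""Layer/module abstractions over the autodiff tensor core.

Follows the familiar layout of larger deep-learning libraries at a fraction
of the surface: ``Module`` tracks parameters (trainable Tensors) and buffers
(running statistics), supports train/eval mode and flat ``state_dict``
serialisation for checkpoints.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, dropout, upsample_nearest2x


class Module:
    """Base class: child modules/parameters are discovered via attributes."""

    def __init__(self):
        self.training = True
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}

    # -- registration -------------------------------------------------------
    def register_parameter(self, name: str, value: Tensor) -> Tensor:
        value.requires_grad = True
        self._params[name] = value
        return value

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        return value

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    # -- traversal ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialisation ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:") :]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: {p.data.shape} vs {value.shape}")
                p.data = value.astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution with He-normal initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        self.stride, self.padding = stride, padding
        self.weight = self.register_parameter(
            "weight", Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        )
        self.bias = self.register_parameter("bias", Tensor(np.zeros(out_ch))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register_parameter("gamma", Tensor(np.ones(channels)))
        self.beta = self.register_parameter("beta", Tensor(np.zeros(channels)))
        self.running_mean = self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.running_var = self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(c)
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(c)
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups, self.eps = groups, eps
        self.gamma = self.register_parameter("gamma", Tensor(np.ones(channels)))
        self.beta = self.register_parameter("beta", Tensor(np.zeros(channels)))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=(2, 3, 4), keepdims=True)
        xhat = ((xg - mu) / ((var + self.eps) ** 0.5)).reshape(n, c, h, w)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class InstanceNorm2d(Module):
    """Per-sample per-channel normalisation; non-affine, as in patch discriminators."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.channels, self.eps = channels, eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.rate, self.rng, self.training)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2x(x)
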