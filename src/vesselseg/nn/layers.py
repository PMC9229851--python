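"""Neural-network layers built on the autodiff tensor.

The registry follows the familiar module pattern: parameters are
``Tensor`` objects with ``requires_grad=True`` found by attribute walking,
running statistics are registered buffers, and ``state_dict`` /
``load_state_dict`` give flat name→array checkpoints.
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor, relu, sigmoid


class Module:
    def __init__(self):
        self.training = True
        self._buffer_names: list[str] = []

    # -- registry ------------------------------------------------------
    def register_buffer(self, name: str, value: np.ndarray):
        setattr(self, name, np.asarray(value, dtype=np.float64))
        self._buffer_names.append(name)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def modules(self):
        """All modules in the tree, this one included."""
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", []):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- modes ---------------------------------------------------------
    def train(self, flag: bool = True):
        self.training = flag
        for _, child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffer_owners = {}
        for name, _ in self.named_buffers():
            *path, leaf = name.split(".")
            owner = self
            for part in path:
                owner = getattr(owner, part)
            buffer_owners[name] = (owner, leaf)
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            elif name in buffer_owners:
                owner, leaf = buffer_owners[name]
                setattr(owner, leaf, np.asarray(value, dtype=np.float64).copy())
            else:
                raise KeyError(f"unknown entry {name!r} in state dict")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        setattr(self, str(len(self._items)), module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2d(Module):
    """Stride-1 transposed convolution (shape-preserving for k=3, p=1)."""

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=1, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.padding = padding
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_channels, out_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x):
        # transposed conv with stride 1 == correlation with the spatially
        # flipped kernel and complementary padding
        w = self.weight.transpose(1, 0, 2, 3).flip_hw()
        return F.conv2d(x, w, self.bias, 1, self.kernel_size - 1 - self.padding, 1)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(
            rng.uniform(-bound, bound, (out_features, in_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x):
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(c)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(c)
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Normalization over the trailing feature axis of token tensors.

    ``enabled=False`` turns the layer into the identity; the attention tests
    use this to reduce the block to textbook self-attention.
    """

    def __init__(self, dim, eps: float = 1e-5, enabled: bool = True):
        super().__init__()
        self.eps, self.enabled = eps, enabled
        self.weight = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x):
        if not self.enabled:
            return x
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.weight + self.bias
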