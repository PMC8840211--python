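"""Neural-network building blocks over the :mod:`rppgnet.autograd` engine.

Provides the module/parameter abstraction, 3-D convolutions (standard,
depth-wise, point-wise and temporal transposed), batch normalization, the
nonlinearities used by the network, and an Adam optimizer.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv3d, pad3d, temporal_dilate

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv3d",
    "TemporalConvTransposeDW",
    "BatchNorm3d",
    "ReLU6",
    "HSwish",
    "Identity",
    "Adam",
]


class Parameter(Tensor):
    """A trainable tensor (always float, always requires grad)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32))
        self.requires_grad = True


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name: str, module: "Module") -> None:
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for mname, m in self._modules.items():
            out.update(m.state_dict(prefix + mname + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=p.data.dtype)
        for name in list(self._buffers):
            arr = np.asarray(state[prefix + name])
            self._buffers[name] = arr
            object.__setattr__(self, name, arr)
        for mname, m in self._modules.items():
            m.load_state_dict(state, prefix + mname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self.add_module(str(i), layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        t = tuple(int(u) for u in v)
        if len(t) != 3:
            raise ValueError(f"expected 3 entries, got {v}")
        return t
    return (int(v),) * 3


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    """Grouped 3-D convolution with 'same'-style symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding=0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.groups = groups
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        rng = rng or np.random.default_rng()
        kt, kh, kw = self.kernel_size
        fan_in = (in_channels // groups) * kt * kh * kw
        self.weight = Parameter(
            kaiming_normal(rng, (out_channels, in_channels // groups, kt, kh, kw), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, groups=self.groups,
        )


class TemporalConvTransposeDW(Module):
    """Per-channel (depth-wise) transposed convolution along time only.

    Kernel (kt, 1, 1), stride (s, 1, 1), padding chosen so the output temporal
    length is exactly ``s`` times the input's (kt = 2s, pad = s/2 convention:
    here kt=4, s=2, pad=1).  Implemented as zero-interleaving followed by a
    unit-stride depth-wise convolution with the time-flipped kernel.
    """

    def __init__(
        self,
        channels: int,
        kernel_size: int = 4,
        stride: int = 2,
        padding: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.channels = channels
        self.kernel_size = int(kernel_size)
        self.stride = int(stride)
        self.padding = int(padding)
        rng = rng or np.random.default_rng()
        self.weight = Parameter(
            kaiming_normal(rng, (channels, 1, self.kernel_size, 1, 1), self.kernel_size)
        )
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        xd = temporal_dilate(x, self.stride)
        pad_t = self.kernel_size - 1 - self.padding
        xd = pad3d(xd, (pad_t, 0, 0))
        # transposed conv correlates with the flipped kernel
        wf = self.weight[:, :, ::-1, :, :]
        out = conv3d(xd, wf, self.bias, stride=(1, 1, 1), padding=(0, 0, 0),
                     groups=self.channels)
        # trim so T_out = stride * T_in exactly
        t_out = self.stride * x.shape[2]
        return out[:, :, :t_out]


class BatchNorm3d(Module):
    """Batch normalization over (B, T, H, W) per channel, with running stats."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, self.num_features, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (mu.data.reshape(-1) - rm)
            rv += self.momentum * (var.data.reshape(-1) - rv)
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self._buffers["running_mean"].reshape(shape)
            var = self._buffers["running_var"].reshape(shape)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu6()


class HSwish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hswish()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
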