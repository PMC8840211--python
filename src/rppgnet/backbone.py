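"""Network assembly and complexity accounting for the rPPG extractor.

The architecture is an encoder-decoder 3-D CNN over facial video volumes
(3 x T x H x W), built from mobilenet-style inverted-residual blocks with 3-D
depth-wise separable convolutions and shuffle attention, followed by a
temporal decoder of depth-wise transposed convolutions, a three-layer fused
ConvGRU, spatial global average pooling and a 1x1x1 head that emits one rPPG
sample per input frame.

Alongside the runnable model, this module carries a closed-form complexity
profiler: multiplication counts for standard and depth-wise separable 3-D
convolutions, and a layer walk that totals multiply-accumulates and trainable
parameters for a :class:`NetworkSpec` without executing a forward pass.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, no_grad
from .convgru import ConvGRUStack
from .nn import (
    BatchNorm3d,
    Conv3d,
    HSwish,
    Identity,
    Module,
    ReLU6,
    Sequential,
    TemporalConvTransposeDW,
)
from .sa3d import ShuffleAttention3D

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ConvComplexity",
    "RPPGNet",
    "std_conv_macs",
    "dw_sep_macs",
    "h_swish",
    "relu6",
    "profile",
    "default_network_spec",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------------
# nonlinearities (scalar/array forms)
# --------------------------------------------------------------------------
def relu6(x):
    return np.minimum(np.maximum(x, 0.0), 6.0)


def h_swish(x):
    """Hard swish: x * ReLU6(x + 3) / 6."""
    x = np.asarray(x, dtype=float)
    out = x * relu6(x + 3.0) / 6.0
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# layer and network specification
# --------------------------------------------------------------------------
_KINDS = ("stem-conv", "eblock", "pwconv", "dcblock", "convgru", "gap", "head-conv")
_NLS = {"relu6": ReLU6, "hswish": HSwish, "none": Identity}


@dataclass(frozen=True)
class LayerSpec:
    """One architecture row: operator kind plus its hyper-parameters."""

    kind: str
    kernel: int = 1                 # cubic kernel extent for conv blocks
    exp: int = 0                    # expansion width inside an eblock
    out: int = 0                    # output channels
    stride: tuple[int, int, int] = (1, 1, 1)   # (temporal, height, width)
    use_sa: bool = False
    nl: str = "none"                # relu6 | hswish | none

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown operator kind {self.kind!r}")
        if self.nl not in _NLS:
            raise ValueError(f"unknown nonlinearity {self.nl!r}")
        if any(s not in (1, 2) for s in self.stride):
            raise ValueError(f"stride entries must be 1 or 2, got {self.stride}")

    def to_line(self) -> str:
        st = "x".join(str(s) for s in self.stride)
        return (
            f"{self.kind}\t{self.kernel}\t{self.exp}\t{self.out}\t{st}"
            f"\t{int(self.use_sa)}\t{self.nl}"
        )

    @classmethod
    def from_line(cls, line: str) -> "LayerSpec":
        kind, kernel, exp, out, st, sa, nl = line.split("\t")
        return cls(
            kind=kind,
            kernel=int(kernel),
            exp=int(exp),
            out=int(out),
            stride=tuple(int(s) for s in st.split("x")),
            use_sa=bool(int(sa)),
            nl=nl,
        )


@dataclass
class NetworkSpec:
    """Ordered layer specs plus the input contract (channels-first video)."""

    layers: list[LayerSpec] = field(default_factory=list)
    in_channels: int = 3
    gru_layers: int = 3
    gru_kernel: int = 3
    sa_groups: int = 4

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"# in_channels={self.in_channels} gru_layers={self.gru_layers} "
            f"gru_kernel={self.gru_kernel} sa_groups={self.sa_groups}\n"
        )
        buf.write("# kind\tkernel\texp\tout\tstride\tsa\tnl\n")
        for layer in self.layers:
            buf.write(layer.to_line() + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "NetworkSpec":
        spec = cls(layers=[])
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tokens in line[1:].split():
                    if "=" in tokens:
                        key, val = tokens.split("=")
                        if hasattr(spec, key):
                            setattr(spec, key, int(val))
                continue
            spec.layers.append(LayerSpec.from_line(line))
        return spec

    # ---------------------------------------------------------------- shapes
    def stride_products(self) -> tuple[int, int, int]:
        """Cumulative (temporal, height, width) downsampling of the encoder."""
        prods = [1, 1, 1]
        for layer in self.layers:
            if layer.kind in ("stem-conv", "eblock"):
                for i in range(3):
                    prods[i] *= layer.stride[i]
        return tuple(prods)

    def validate_input(self, shape: tuple[int, int, int, int]) -> None:
        C, T, H, W = shape
        td, hd, wd = self.stride_products()
        problems = []
        if C != self.in_channels:
            problems.append(f"channels={C} (expected {self.in_channels})")
        if T % td:
            problems.append(f"temporal length={T} not divisible by {td}")
        if H % hd:
            problems.append(f"height={H} not a multiple of {hd}")
        if W % wd:
            problems.append(f"width={W} not a multiple of {wd}")
        if problems:
            raise ValueError("invalid input shape: " + "; ".join(problems))

    def propagate_shapes(
        self, input_shape: tuple[int, int, int, int]
    ) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        """(C, T, H, W) in/out shape pairs for every layer, closed form."""

        def down(n, s):  # 'same' padding, odd kernel
            return (n - 1) // s + 1

        shapes = []
        C, T, H, W = input_shape
        for layer in self.layers:
            cin = (C, T, H, W)
            st, sh, sw = layer.stride
            if layer.kind in ("stem-conv", "eblock"):
                C, T, H, W = layer.out, down(T, st), down(H, sh), down(W, sw)
            elif layer.kind == "pwconv":
                C = layer.out
            elif layer.kind == "dcblock":
                C, T = layer.out, T * st
            elif layer.kind == "convgru":
                C = layer.out
            elif layer.kind == "gap":
                H = W = 1
            elif layer.kind == "head-conv":
                C = layer.out
            shapes.append((cin, (C, T, H, W)))
        return shapes


def default_network_spec() -> NetworkSpec:
    """The published architecture table (input 3 x 128 x 128 x 128)."""
    E = LayerSpec
    layers = [
        E("stem-conv", kernel=3, out=16, stride=(1, 2, 2), nl="relu6"),
        E("eblock", 3, 16, 16, (1, 2, 2), True, "relu6"),
        E("eblock", 3, 72, 24, (1, 2, 2), False, "relu6"),
        E("eblock", 3, 88, 24, (1, 1, 1), False, "relu6"),
        E("eblock", 5, 96, 40, (2, 2, 2), True, "hswish"),
        E("eblock", 5, 240, 40, (1, 1, 1), True, "hswish"),
        E("eblock", 5, 240, 40, (1, 1, 1), True, "hswish"),
        E("eblock", 5, 120, 48, (1, 1, 1), True, "hswish"),
        E("eblock", 5, 144, 48, (1, 1, 1), True, "hswish"),
        E("eblock", 5, 288, 96, (2, 2, 2), True, "hswish"),
        E("eblock", 5, 576, 96, (1, 1, 1), True, "hswish"),
        E("eblock", 5, 576, 96, (1, 1, 1), True, "hswish"),
        E("pwconv", 1, 0, 576, (1, 1, 1), False, "hswish"),
        E("dcblock", 4, 0, 288, (2, 1, 1), False, "hswish"),
        E("dcblock", 4, 0, 144, (2, 1, 1), False, "hswish"),
        E("convgru", out=64),
        E("gap", out=64),
        E("head-conv", kernel=1, out=1),
    ]
    return NetworkSpec(layers=layers)


# --------------------------------------------------------------------------
# complexity formulas
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ConvComplexity:
    """Shape summary of one 3-D convolution for multiplication counting."""

    Df: int   # spatial extent of the input feature map
    Dg: int   # spatial extent of the output feature map
    Dk: int   # cubic kernel extent
    M: int    # input channels
    N: int    # output channels
    T: int    # temporal extent

    def __post_init__(self):
        for name in ("Df", "Dg", "Dk", "M", "N", "T"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


def std_conv_macs(c: ConvComplexity) -> int:
    """Multiplications of a standard 3-D convolution: Dk^3 Dg^2 M N T."""
    return c.Dk**3 * c.Dg**2 * c.M * c.N * c.T


def dw_sep_macs(c: ConvComplexity) -> int:
    """Multiplications of a depth-wise separable 3-D convolution.

    Depth-wise part Dk^3 Dg^2 M T plus point-wise part Dg^2 M N T; the ratio
    to the standard convolution is 1/N + 1/Dk^3.
    """
    return c.Dk**3 * c.Dg**2 * c.M * c.T + c.Dg**2 * c.M * c.N * c.T


# --------------------------------------------------------------------------
# profiler
# --------------------------------------------------------------------------
def _conv_entry(name, out_elems, k, cin_per_group, cout, bias, bn=False):
    macs = out_elems * k * cin_per_group
    params = cout * cin_per_group * k + (cout if bias else 0)
    if bn:
        params += 2 * cout
    return {"layer": name, "macs": int(macs), "params": int(params)}


def profile(
    spec: NetworkSpec, input_shape: tuple[int, int, int, int]
) -> tuple[int, int, list[dict]]:
    """Walk the network closed-form and total multiplications and parameters.

    Counting convention: one unit per multiply-accumulate of the convolution,
    transposed-convolution and ConvGRU convolution layers.  Normalization,
    nonlinearities, pooling and attention gating contribute parameters (where
    trainable) but no MACs — the multiplications-only convention of the
    separable-convolution complexity formulas.

    Returns (total_macs, total_params, per-layer table).
    """
    table: list[dict] = []
    shapes = spec.propagate_shapes(input_shape)
    for idx, (layer, (sin, sout)) in enumerate(zip(spec.layers, shapes)):
        cin, tin, hin, win = sin
        cout, tout, hout, wout = sout
        name = f"{idx}:{layer.kind}"
        if layer.kind == "stem-conv":
            out_elems = cout * tout * hout * wout
            table.append(
                _conv_entry(name, out_elems, layer.kernel**3, cin, cout, False, bn=True)
            )
        elif layer.kind == "eblock":
            exp = layer.exp
            # point-wise expansion at input resolution
            e1 = _conv_entry(f"{name}.pw1", exp * tin * hin * win, 1, cin, exp, False, bn=True)
            # depth-wise at output resolution
            e2 = _conv_entry(
                f"{name}.dw", exp * tout * hout * wout, layer.kernel**3, 1, exp, False, bn=True
            )
            e2["params"] = exp * layer.kernel**3 + 2 * exp  # one kernel per channel
            # point-wise projection
            e3 = _conv_entry(f"{name}.pw2", cout * tout * hout * wout, 1, exp, cout, False, bn=True)
            table.extend([e1, e2, e3])
            if layer.use_sa:
                # scale/shift pairs of both branches plus the GN affine: 3 per
                # pair of channels -> 3 * exp parameters, no counted MACs
                table.append({"layer": f"{name}.sa", "macs": 0, "params": 3 * exp})
        elif layer.kind == "pwconv":
            out_elems = cout * tout * hout * wout
            table.append(_conv_entry(name, out_elems, 1, cin, cout, False, bn=True))
        elif layer.kind == "dcblock":
            st = layer.stride[0]
            in_elems = cin * tin * hin * win
            # depth-wise temporal transposed conv: every input element meets
            # every one of the k temporal taps of its channel's kernel
            e1 = {
                "layer": f"{name}.dwT",
                "macs": int(in_elems * layer.kernel),
                "params": cin * layer.kernel + 2 * cin,
            }
            e2 = _conv_entry(
                f"{name}.pw", cout * (tin * st) * hin * win, 1, cin, cout, False, bn=True
            )
            table.extend([e1, e2])
        elif layer.kind == "convgru":
            k2 = spec.gru_kernel**2
            ch = layer.out
            macs = params = 0
            c_in = cin
            for _ in range(spec.gru_layers):
                per_step = hout * wout
                macs += 3 * k2 * c_in * ch * tout * per_step      # input convs
                macs += 3 * k2 * ch * ch * tout * per_step        # hidden convs
                params += 3 * (k2 * c_in * ch + ch) + 3 * k2 * ch * ch
                c_in = ch
            table.append({"layer": name, "macs": int(macs), "params": int(params)})
        elif layer.kind == "gap":
            table.append({"layer": name, "macs": 0, "params": 0})
        elif layer.kind == "head-conv":
            out_elems = cout * tout * hout * wout
            table.append(_conv_entry(name, out_elems, 1, cin, cout, True, bn=False))
        else:  # pragma: no cover
            raise ValueError(f"unknown operator kind {layer.kind!r}")
    total_macs = int(sum(r["macs"] for r in table))
    total_params = int(sum(r["params"] for r in table))
    return total_macs, total_params, table


# --------------------------------------------------------------------------
# runnable model
# --------------------------------------------------------------------------
class EBlock(Module):
    """Inverted residual: PW expand -> DW conv -> (attention) -> PW project.

    The identity skip is added only when the stride is (1,1,1) and input and
    output channel counts match (mobilenet-v2 rule).
    """

    def __init__(self, cin: int, spec: LayerSpec, sa_groups: int, rng):
        super().__init__()
        exp, cout, k = spec.exp, spec.out, spec.kernel
        pad = k // 2
        nl = _NLS[spec.nl]
        self.skip = spec.stride == (1, 1, 1) and cin == cout
        self.expand = Sequential(
            Conv3d(cin, exp, 1, bias=False, rng=rng), BatchNorm3d(exp), nl()
        )
        self.depthwise = Sequential(
            Conv3d(exp, exp, k, stride=spec.stride, padding=pad, groups=exp,
                   bias=False, rng=rng),
            BatchNorm3d(exp),
            nl(),
        )
        self.attn = ShuffleAttention3D(exp, sa_groups) if spec.use_sa else Identity()
        self.project = Sequential(
            Conv3d(exp, cout, 1, bias=False, rng=rng), BatchNorm3d(cout)
        )

    def forward(self, x: Tensor) -> Tensor:
        y = self.project(self.attn(self.depthwise(self.expand(x))))
        return x + y if self.skip else y


class DCBlock(Module):
    """Temporal decoder block: depth-wise transposed conv (2x temporal
    upsampling) followed by a point-wise channel projection."""

    def __init__(self, cin: int, spec: LayerSpec, rng):
        super().__init__()
        nl = _NLS[spec.nl]
        self.up = Sequential(
            TemporalConvTransposeDW(cin, spec.kernel, spec.stride[0], 1,
                                    bias=False, rng=rng),
            BatchNorm3d(cin),
            nl(),
        )
        self.project = Sequential(
            Conv3d(cin, spec.out, 1, bias=False, rng=rng),
            BatchNorm3d(spec.out),
            nl(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.up(x))


class RPPGNet(Module):
    """The full video-to-waveform network, built from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        super().__init__()
        self.spec = spec or default_network_spec()
        rng = np.random.default_rng(seed)
        shapes = self.spec.propagate_shapes((self.spec.in_channels, 128, 128, 128))
        self.blocks: list[Module] = []
        for idx, (layer, (sin, _)) in enumerate(zip(self.spec.layers, shapes)):
            cin = sin[0]
            if layer.kind == "stem-conv":
                block = Sequential(
                    Conv3d(cin, layer.out, layer.kernel, stride=layer.stride,
                           padding=layer.kernel // 2, bias=False, rng=rng),
                    BatchNorm3d(layer.out),
                    _NLS[layer.nl](),
                )
            elif layer.kind == "eblock":
                block = EBlock(cin, layer, self.spec.sa_groups, rng)
            elif layer.kind == "pwconv":
                block = Sequential(
                    Conv3d(cin, layer.out, 1, bias=False, rng=rng),
                    BatchNorm3d(layer.out),
                    _NLS[layer.nl](),
                )
            elif layer.kind == "dcblock":
                block = DCBlock(cin, layer, rng)
            elif layer.kind == "convgru":
                block = ConvGRUStack(cin, layer.out, self.spec.gru_layers,
                                     self.spec.gru_kernel, rng=rng)
            elif layer.kind == "gap":
                block = _SpatialGAP()
            elif layer.kind == "head-conv":
                block = Conv3d(cin, layer.out, 1, bias=True, rng=rng)
            else:  # pragma: no cover
                raise ValueError(layer.kind)
            self.blocks.append(block)
            self.add_module(f"block{idx}", block)

    def forward(self, video, shape_hook=None) -> Tensor:
        """Map a (B, 3, T, H, W) or (3, T, H, W) volume to a (B, T) trace."""
        x = as_tensor(video)
        if x.ndim == 4:
            x = x.reshape((1, *x.shape))
        self.spec.validate_input(x.shape[1:])
        for idx, block in enumerate(self.blocks):
            x = block(x)
            if shape_hook is not None:
                shape_hook(idx, x.shape)
        # (B, 1, T, 1, 1) -> (B, T)
        return x.reshape(x.shape[0], x.shape[2])

    def infer(self, video) -> np.ndarray:
        """Inference without graph construction; returns a (B, T) array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(video)
        finally:
            self.train(was_training)
        return out.data


class _SpatialGAP(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(3, 4), keepdims=True)


# --------------------------------------------------------------------------
# checkpoint I/O
# --------------------------------------------------------------------------
def save_checkpoint(path, model: RPPGNet, extra: dict | None = None) -> None:
    """Archive all weights, buffers and the network spec in a single file."""
    state = model.state_dict()
    state["__spec__"] = np.frombuffer(model.spec.to_text().encode(), dtype=np.uint8)
    if extra:
        for key, val in extra.items():
            state[f"__extra__{key}"] = np.asarray(val)
    np.savez(path, **state)


def load_checkpoint(path) -> RPPGNet:
    with np.load(path) as data:
        spec = NetworkSpec.from_text(bytes(data["__spec__"]).decode())
        model = RPPGNet(spec)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.load_state_dict(state)
    return model
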