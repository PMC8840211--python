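"""Convolutional gated recurrent units over per-frame feature maps.

A ConvGRU cell replaces the dense transforms of a GRU with spatially
zero-padded 2-D convolutions, so the hidden state keeps the (C, H, W) geometry
of the feature maps while accumulating temporal context:

    z_t = sigmoid(Wz * x_t + Uz * h_{t-1})
    r_t = sigmoid(Wr * x_t + Ur * h_{t-1})
    h~_t = tanh(W * x_t + U * (r_t . h_{t-1}))
    h_t = (1 - z_t) . h_{t-1} + z_t . h~_t

(* is convolution, . elementwise product).  With 1x1 kernels on a 1x1 grid the
cell reduces exactly to the dense scalar GRU, which the tests exploit as an
independent oracle.

The three-layer stack fuses the per-time-step hidden states of its layers by
an elementwise mean (all layers share one hidden width, so the fused output
keeps that width).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concatenate, conv3d
from .nn import Conv3d, Module

__all__ = ["ConvGRUCell", "ConvGRUStack", "dense_gru_step"]


def dense_gru_step(x, h_prev, Wz, Uz, Wr, Ur, W, U, bz=0.0, br=0.0, bh=0.0):
    """Scalar/dense GRU step on numpy arrays — oracle for the 1x1-kernel cell."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    z = sig(Wz * x + Uz * h_prev + bz)
    r = sig(Wr * x + Ur * h_prev + br)
    h_tilde = np.tanh(W * x + U * (r * h_prev) + bh)
    return (1.0 - z) * h_prev + z * h_tilde


class ConvGRUCell(Module):
    """One ConvGRU cell: 3 input-to-hidden + 3 hidden-to-hidden 2-D convs.

    Kernels must have odd extent so zero padding keeps the spatial size of the
    hidden state constant over time.
    """

    def __init__(
        self,
        in_channels: int,
        hidden_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel extent must be odd to preserve spatial size")
        self.in_channels = in_channels
        self.hidden_channels = hidden_channels
        self.kernel_size = kernel_size
        rng = rng or np.random.default_rng()
        pad = kernel_size // 2
        k3 = (1, kernel_size, kernel_size)
        p3 = (0, pad, pad)

        def conv(cin, cout, bias):
            return Conv3d(cin, cout, k3, padding=p3, bias=bias, rng=rng)

        # gate biases live on the input convolutions (one bias per gate)
        self.wz = conv(in_channels, hidden_channels, True)
        self.wr = conv(in_channels, hidden_channels, True)
        self.w = conv(in_channels, hidden_channels, True)
        self.uz = conv(hidden_channels, hidden_channels, False)
        self.ur = conv(hidden_channels, hidden_channels, False)
        self.u = conv(hidden_channels, hidden_channels, False)

    def init_hidden(self, batch: int, H: int, W: int, dtype=np.float32) -> Tensor:
        return Tensor(np.zeros((batch, self.hidden_channels, 1, H, W), dtype=dtype))

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        """One time step; x_t and h_prev are (B, C, 1, H, W)."""
        if x_t.shape[-2:] != h_prev.shape[-2:]:
            raise ValueError(
                f"spatial size mismatch: input {x_t.shape[-2:]} vs hidden {h_prev.shape[-2:]}"
            )
        z = (self.wz(x_t) + self.uz(h_prev)).sigmoid()
        r = (self.wr(x_t) + self.ur(h_prev)).sigmoid()
        h_tilde = (self.w(x_t) + self.u(r * h_prev)).tanh()
        return (1.0 - z) * h_prev + z * h_tilde

    def forward(self, xs: Tensor, h0: Tensor | None = None) -> Tensor:
        """Run the cell over a (B, C, T, H, W) sequence; returns (B, Ch, T, H, W).

        The input-to-hidden convolutions are precomputed for all time steps at
        once (they do not depend on the recurrence); only the hidden-to-hidden
        convolutions run step by step.
        """
        xs = as_tensor(xs)
        B, C, T, H, W = xs.shape
        if T < 1:
            raise ValueError("empty sequence")
        h = self.init_hidden(B, H, W, dtype=xs.dtype) if h0 is None else h0
        ch = self.hidden_channels
        pad = (0, self.kernel_size // 2, self.kernel_size // 2)
        # fused input transform for all gates over the whole sequence
        w_in = concatenate([self.wz.weight, self.wr.weight, self.w.weight], axis=0)
        b_in = concatenate([self.wz.bias, self.wr.bias, self.w.bias], axis=0)
        a = conv3d(xs, w_in, b_in, padding=pad)
        # fused z/r hidden transform (the candidate's needs r, so stays apart)
        w_zr = concatenate([self.uz.weight, self.ur.weight], axis=0)
        outs = []
        for t in range(T):
            at = a[:, :, t : t + 1]
            uzr = conv3d(h, w_zr, None, padding=pad)
            z = (at[:, :ch] + uzr[:, :ch]).sigmoid()
            r = (at[:, ch : 2 * ch] + uzr[:, ch:]).sigmoid()
            h_tilde = (at[:, 2 * ch :] + self.u(r * h)).tanh()
            h = (1.0 - z) * h + z * h_tilde
            outs.append(h)
        return concatenate(outs, axis=2)


class ConvGRUStack(Module):
    """Stack of ConvGRU layers whose per-step outputs are fused by a mean.

    Layer l consumes layer l-1's hidden-state sequence; all layers share one
    hidden width so the elementwise mean is well-defined.
    """

    def __init__(
        self,
        in_channels: int,
        hidden_channels: int = 64,
        num_layers: int = 3,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.num_layers = num_layers
        self.hidden_channels = hidden_channels
        self.cells = []
        for i in range(num_layers):
            cin = in_channels if i == 0 else hidden_channels
            cell = ConvGRUCell(cin, hidden_channels, kernel_size, rng=rng)
            self.cells.append(cell)
            self.add_module(f"cell{i}", cell)

    def forward(self, xs: Tensor) -> Tensor:
        layer_outs = []
        h = as_tensor(xs)
        for cell in self.cells:
            h = cell(h)
            layer_outs.append(h)
        out = layer_outs[0]
        for lo in layer_outs[1:]:
            out = out + lo
        return out * (1.0 / len(layer_outs))
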