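"""3-D shuffle attention: grouped channel + spatial attention with channel shuffle.

The block splits a (C, T, H, W) feature volume into G groups of channels,
halves each group into a channel-attention branch and a spatial-attention
branch, gates each branch with a per-channel sigmoid (driven by a global
average pool for the channel branch and a group-normalized map for the spatial
branch), re-concatenates, and finally shuffles channels so information flows
across groups.  The output shape always equals the input shape, so the block
can be inserted anywhere in a 3-D feature stack.

Functional forms here accept plain numpy arrays (analysis / testing) while the
:class:`ShuffleAttention3D` module runs on autograd tensors for training.
"""

from __future__ import annotations

import logging

import numpy as np

from .autograd import Tensor, as_tensor, concatenate
from .nn import Module, Parameter

__all__ = [
    "group_split",
    "global_avg_pool",
    "channel_branch",
    "spatial_branch",
    "channel_shuffle",
    "sa_block",
    "ShuffleAttention3D",
    "effective_groups",
    "InvalidGroupingError",
]

log = logging.getLogger(__name__)


class InvalidGroupingError(ValueError):
    """Raised when the group count is incompatible with the channel count."""


def _check_grouping(C: int, G: int) -> None:
    if G < 1 or C % G != 0:
        raise InvalidGroupingError(f"G={G} does not divide C={C}")
    if C // (2 * G) < 1:
        raise InvalidGroupingError(f"C={C}, G={G}: sub-branches would be empty")


def effective_groups(C: int, G: int) -> int:
    """Largest G' <= G that divides C with C/(2G') >= 1 (clamp for thin layers)."""
    g = min(G, C // 2) if C >= 2 else 1
    while g > 1 and (C % g or C // (2 * g) < 1):
        g -= 1
    if g != G:
        log.debug("shuffle attention: clamped G=%d to %d for C=%d", G, g, C)
    return max(g, 1)


def group_split(x: np.ndarray, G: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split channels into G groups, each halved into (Xk1, Xk2) branches."""
    C = x.shape[0]
    _check_grouping(C, G)
    cg = C // G
    half = cg // 2
    out = []
    for k in range(G):
        grp = x[k * cg : (k + 1) * cg]
        out.append((grp[:half], grp[half:]))
    return out


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Per-channel mean over the (T, H, W) extent: (C, T, H, W) -> (C,)."""
    if x.size == 0:
        raise ValueError("empty sub-volume")
    return x.mean(axis=(1, 2, 3))


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def channel_branch(xk1: np.ndarray, w1: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """Gate each channel by sigmoid(w1 * GAP(x) + b1)."""
    C = xk1.shape[0]
    w1, b1 = np.asarray(w1), np.asarray(b1)
    if w1.shape != (C,) or b1.shape != (C,):
        raise ValueError(f"channel parameters must have shape ({C},)")
    s = global_avg_pool(xk1)
    gate = _sigmoid(w1 * s + b1)
    return gate[:, None, None, None] * xk1


def spatial_branch(
    xk2: np.ndarray, w2: np.ndarray, b2: np.ndarray, eps: float = 1e-5
) -> np.ndarray:
    """Gate each voxel by sigmoid(w2 * GN(x) + b2), GN per channel over T,H,W."""
    C = xk2.shape[0]
    w2, b2 = np.asarray(w2), np.asarray(b2)
    if w2.shape != (C,) or b2.shape != (C,):
        raise ValueError(f"spatial parameters must have shape ({C},)")
    mu = xk2.mean(axis=(1, 2, 3), keepdims=True)
    var = xk2.var(axis=(1, 2, 3), keepdims=True)
    gn = (xk2 - mu) / np.sqrt(var + eps)
    gate = _sigmoid(w2[:, None, None, None] * gn + b2[:, None, None, None])
    return gate * xk2


def channel_shuffle(x: np.ndarray, G: int) -> np.ndarray:
    """Reshape channels (C,) -> (G, C/G), transpose, flatten (ShuffleNet-v2).

    A pure permutation of channel slices; shuffling with the swapped factor
    C/G inverts it.
    """
    C = x.shape[0]
    if G < 1 or C % G != 0:
        raise InvalidGroupingError(f"G={G} does not divide C={C}")
    perm = np.arange(C).reshape(G, C // G).T.reshape(-1)
    return x[perm]


def sa_block(
    x: np.ndarray,
    G: int,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
    eps: float = 1e-5,
) -> np.ndarray:
    """Full shuffle-attention pipeline on a (C, T, H, W) array.

    Parameter vectors are laid out group-major: entry ``k * C/(2G) + c`` is the
    parameter for channel ``c`` of group ``k``'s branch.
    """
    C = x.shape[0]
    _check_grouping(C, G)
    half = C // (2 * G)
    pieces = []
    for k, (xk1, xk2) in enumerate(group_split(x, G)):
        sl = slice(k * half, (k + 1) * half)
        pieces.append(channel_branch(xk1, w1[sl], b1[sl]))
        pieces.append(spatial_branch(xk2, w2[sl], b2[sl], eps))
    return channel_shuffle(np.concatenate(pieces, axis=0), G)


class ShuffleAttention3D(Module):
    """Trainable 3-D shuffle attention over (B, C, T, H, W) tensors.

    Channel-branch scale/shift start at (0, 0) and spatial-branch at (1, 0)
    so the block begins near-neutral (every gate ~0.5 to ~sigmoid(GN)).
    """

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.groups = effective_groups(channels, groups)
        _check_grouping(channels, self.groups)
        self.eps = eps
        half_total = channels // 2
        self.w1 = Parameter(np.zeros(half_total))
        self.b1 = Parameter(np.zeros(half_total))
        self.w2 = Parameter(np.ones(half_total))
        self.b2 = Parameter(np.zeros(half_total))
        # per-channel affine of the group normalization in the spatial branch
        self.gn_weight = Parameter(np.ones(half_total))
        self.gn_bias = Parameter(np.zeros(half_total))
        perm = np.arange(channels).reshape(self.groups, channels // self.groups)
        self._perm = perm.T.reshape(-1)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        B, C, T, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        G = self.groups
        cg = C // G
        half = cg // 2
        sh = (1, -1, 1, 1, 1)
        pieces = []
        for k in range(G):
            grp = x[:, k * cg : (k + 1) * cg]
            xk1 = grp[:, :half]
            xk2 = grp[:, half:]
            sl = slice(k * half, (k + 1) * half)
            # channel branch: sigmoid(w1 * GAP + b1) gate
            s = xk1.mean(axis=(2, 3, 4), keepdims=True)
            gate1 = (self.w1[sl].reshape(sh) * s + self.b1[sl].reshape(sh)).sigmoid()
            pieces.append(gate1 * xk1)
            # spatial branch: sigmoid(w2 * GN + b2) gate
            mu = xk2.mean(axis=(2, 3, 4), keepdims=True)
            xc = xk2 - mu
            var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
            gn = xc * ((var + self.eps) ** -0.5)
            gn = gn * self.gn_weight[sl].reshape(sh) + self.gn_bias[sl].reshape(sh)
            gate2 = (self.w2[sl].reshape(sh) * gn + self.b2[sl].reshape(sh)).sigmoid()
            pieces.append(gate2 * xk2)
        out = concatenate(pieces, axis=1)
        return out[:, self._perm]
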