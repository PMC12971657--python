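"""Windowed multi-head self-attention variants over 2D feature maps.

Four partition geometries are supported, one per wavelet subband branch:

* ``WB`` - big square windows (degenerates to global attention when the
  map fits in one window),
* ``WS`` - small square windows,
* ``SH`` - horizontal stripes (full-width bands of ``window`` rows),
* ``SV`` - vertical stripes (full-height bands of ``window`` columns).

Consecutive blocks alternate between unshifted and shifted partitions.
Shifting is realized Swin-style: the grid is cyclically rolled by the
shift, tiled with aligned windows, and an attention mask forbids pairs of
tokens whose pre-roll regions differ, which is exactly equivalent to
running unmasked attention on each region of the shifted partition.
Ragged extents are padded with mask-excluded dummy tokens so that the
partition remains a bijection on real tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from . import tensor as T
from .tensor import Tensor

VARIANTS = ("WB", "WS", "SH", "SV")
_MASK_NEG = -1e9


@dataclass(frozen=True)
class AttentionSpec:
    """Geometry of one attention branch.

    ``window`` is the square side for WB/WS and the stripe thickness for
    SH/SV; ``shift`` must satisfy ``0 <= shift < window`` (the block
    schedule uses 0 or ``window // 2``).
    """

    variant: str
    window: int
    shift: int = 0
    heads: int = 1

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown attention variant {self.variant!r}")
        if self.window < 1:
            raise ValueError("window must be positive")
        if not (0 <= self.shift < self.window):
            raise ValueError("shift must satisfy 0 <= shift < window")
        if self.heads < 1:
            raise ValueError("heads must be positive")


@dataclass
class WindowPartition:
    """Precomputed grouping of an H x W grid for one AttentionSpec."""

    height: int
    width: int
    tile: tuple          # (wh, ww) actual window extent after clamping
    shifts: tuple        # (row shift, col shift) actually applied
    index: np.ndarray    # (n_groups, S) flat token ids, -1 for dummies
    mask: np.ndarray     # (n_groups, S, S) admissible pairs
    region_ids: np.ndarray  # (H, W) pre-roll region id of every token
    inverse: np.ndarray  # (H*W,) position of token t in flattened groups

    @property
    def groups(self):
        """Token-index lists (dummies stripped), the partition's group view."""
        return [row[row >= 0].tolist() for row in self.index]


def _axis_geometry(extent: int, window: int, shift: int):
    w = min(window, extent)
    s = shift if (shift < w and w < extent) else 0
    return w, s


def partition(height: int, width: int, spec: AttentionSpec) -> WindowPartition:
    """Build the (possibly shifted) window partition for an H x W grid."""
    if height < 1 or width < 1:
        raise ValueError(f"non-positive grid {height}x{width}")
    if spec.variant in ("WB", "WS"):
        wh, sr = _axis_geometry(height, spec.window, spec.shift)
        ww, sc = _axis_geometry(width, spec.window, spec.shift)
    elif spec.variant == "SH":
        wh, sr = _axis_geometry(height, spec.window, spec.shift)
        ww, sc = width, 0
    else:  # SV
        wh, sr = height, 0
        ww, sc = _axis_geometry(width, spec.window, spec.shift)

    ids = np.arange(height * width, dtype=np.int64).reshape(height, width)
    rid_row = (np.arange(height) - sr) // wh
    rid_col = (np.arange(width) - sc) // ww
    region = rid_row[:, None] * (width // ww + 3) + rid_col[None, :]

    rolled_ids = np.roll(ids, (-sr, -sc), axis=(0, 1))
    rolled_reg = np.roll(region, (-sr, -sc), axis=(0, 1))

    hp = -(-height // wh) * wh
    wp = -(-width // ww) * ww
    pad_ids = np.full((hp, wp), -1, dtype=np.int64)
    pad_reg = np.full((hp, wp), np.iinfo(np.int64).min, dtype=np.int64)
    pad_ids[:height, :width] = rolled_ids
    pad_reg[:height, :width] = rolled_reg

    def _tiles(arr):
        return (arr.reshape(hp // wh, wh, wp // ww, ww)
                .transpose(0, 2, 1, 3)
                .reshape(-1, wh * ww))

    index = _tiles(pad_ids)
    reg = _tiles(pad_reg)
    valid = index >= 0
    mask = ((reg[:, :, None] == reg[:, None, :])
            & valid[:, :, None] & valid[:, None, :])
    s = wh * ww
    mask |= np.eye(s, dtype=bool)[None]  # dummies self-attend (softmax safety)

    inverse = np.full(height * width, -1, dtype=np.int64)
    flat_idx = index.reshape(-1)
    pos = np.arange(flat_idx.size, dtype=np.int64)
    inverse[flat_idx[flat_idx >= 0]] = pos[flat_idx >= 0]
    return WindowPartition(height, width, (wh, ww), (sr, sc),
                           index, mask, region, inverse)


def _relative_index(wh: int, ww: int) -> np.ndarray:
    """(S, S) index into a ((2wh-1)(2ww-1),) bias table by in-tile offsets."""
    coords = np.stack(np.meshgrid(np.arange(wh), np.arange(ww), indexing="ij"),
                      axis=-1).reshape(-1, 2)
    rel = coords[:, None, :] - coords[None, :, :]
    return ((rel[..., 0] + wh - 1) * (2 * ww - 1)
            + (rel[..., 1] + ww - 1)).astype(np.int64)


class WindowMSA(nn.Module):
    """Multi-head self-attention over one window partition.

    Built for a fixed grid extent so the partition, mask and
    relative-position-bias geometry are precomputed once.  The bias table
    is a learnable per-head lookup over in-window offsets, zero-initialized.
    """

    def __init__(self, channels: int, spec: AttentionSpec,
                 height: int, width: int,
                 rng: np.random.Generator | None = None,
                 zero_init_proj: bool = False):
        super().__init__()
        if channels % spec.heads:
            raise ValueError(
                f"channels {channels} not divisible by heads {spec.heads}")
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.channels = channels
        self.head_dim = channels // spec.heads
        self.part = partition(height, width, spec)
        wh, ww = self.part.tile
        self.qkv = nn.Linear(channels, 3 * channels, rng=rng)
        self.proj = nn.Linear(channels, channels, rng=rng,
                              zero_init=zero_init_proj)
        self.bias_table = nn.parameter(
            np.zeros(((2 * wh - 1) * (2 * ww - 1), spec.heads)))
        self._rel_index = _relative_index(wh, ww)
        self._mask_bias = np.where(self.part.mask[:, None, :, :], 0.0,
                                   _MASK_NEG).astype(np.float32)
        self._gather_idx = np.where(self.part.index < 0,
                                    height * width, self.part.index)

    def forward(self, x: Tensor) -> Tensor:
        x = T.astensor(x)
        b, h, w, c = x.shape
        if (h, w) != (self.part.height, self.part.width):
            raise ValueError(f"expected {self.part.height}x{self.part.width} "
                             f"map, got {h}x{w}")
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        ng, s = self._gather_idx.shape
        heads, hd = self.spec.heads, self.head_dim

        xf = x.reshape(b, h * w, c)
        xf = T.concat([xf, Tensor(np.zeros((b, 1, c), dtype=np.float32))],
                      axis=1)  # dummy-token row
        g = T.take(xf, self._gather_idx.reshape(-1), axis=1)
        qkv = self.qkv(g).reshape(b, ng, s, 3, heads, hd)
        qkv = qkv.transpose(3, 0, 1, 4, 2, 5)  # (3, b, ng, heads, s, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]

        attn = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
        bias = T.take(self.bias_table, self._rel_index.reshape(-1), axis=0)
        bias = bias.reshape(s, s, heads).transpose(2, 0, 1)  # (heads, s, s)
        attn = attn + bias + Tensor(self._mask_bias)
        attn = nn.softmax(attn, axis=-1)
        out = attn @ v  # (b, ng, heads, s, hd)
        out = out.transpose(0, 1, 3, 2, 4).reshape(b, ng * s, c)
        out = T.take(out, self.part.inverse, axis=1).reshape(b, h, w, c)
        return self.proj(out)


def msa(x, module: WindowMSA) -> Tensor:
    """Functional wrapper: apply one windowed-attention module to ``x``."""
    return module(x)


# ---------------------------------------------------------------------------
# Reference (dense, group-by-group) path and the shift-equivalence check
# ---------------------------------------------------------------------------

def preroll_group_attention(x: np.ndarray, module: WindowMSA) -> np.ndarray:
    """Unmasked dense attention run separately on each pre-roll region.

    Uses the module's weights but none of its rolling/masking machinery:
    every region of the shifted partition is processed as an independent
    dense attention problem with the relative-position bias looked up from
    true spatial offsets.  By the Swin masking construction this must equal
    the module's rolled-and-masked forward pass token for token.
    """
    x = np.asarray(x, dtype=np.float64)
    b, h, w, c = x.shape
    heads, hd = module.spec.heads, module.head_dim
    wh, ww = module.part.tile
    wq = module.qkv.weight.data.astype(np.float64)
    bq = module.qkv.bias.data.astype(np.float64)
    wp = module.proj.weight.data.astype(np.float64)
    bp = module.proj.bias.data.astype(np.float64)
    table = module.bias_table.data.astype(np.float64)

    region = module.part.region_ids
    out = np.zeros_like(x)
    for rid in np.unique(region):
        rows, cols = np.nonzero(region == rid)
        tokens = x[:, rows, cols, :]              # (b, n, c)
        qkv = tokens @ wq + bq
        q, k, v = np.split(qkv, 3, axis=-1)
        n = tokens.shape[1]
        dr = rows[:, None] - rows[None, :]
        dc = cols[:, None] - cols[None, :]
        bias = table[(dr + wh - 1) * (2 * ww - 1) + (dc + ww - 1)]  # (n,n,heads)
        for hh in range(heads):
            sl = slice(hh * hd, (hh + 1) * hd)
            scores = q[..., sl] @ k[..., sl].swapaxes(-1, -2) / np.sqrt(hd)
            scores = scores + bias[None, :, :, hh]
            scores -= scores.max(axis=-1, keepdims=True)
            p = np.exp(scores)
            p /= p.sum(axis=-1, keepdims=True)
            out[:, rows, cols, sl.start:sl.stop] = p @ v[..., sl]
    return out @ wp + bp


def shifted_equivalence_check(x, spec: AttentionSpec,
                              seed: int = 0, tol: float = 1e-5) -> bool:
    """True iff masked attention on the rolled grid matches unmasked
    attention run independently on every pre-roll window group."""
    x = np.asarray(x, dtype=np.float32)
    b, h, w, c = x.shape
    rng = np.random.default_rng(seed)
    module = WindowMSA(c, spec, h, w, rng=rng)
    module.bias_table.data = rng.standard_normal(
        module.bias_table.data.shape).astype(np.float32) * 0.1
    with T.no_grad():
        fast = module(Tensor(x)).data
    ref = preroll_group_attention(x, module)
    return bool(np.abs(fast - ref).max() <= tol)
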