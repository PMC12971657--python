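"""Composite backbone blocks.

``FGTBlock`` — frequency-aware global-local transformer block: LayerNorm,
single-level Haar decomposition, one dedicated windowed-attention branch
per subband (approximation -> big windows, horizontal detail -> horizontal
stripes, vertical detail -> vertical stripes, diagonal detail -> small
windows), inverse transform, residual, FFN.

``SwinBlock`` — the plain spatial windowed-attention block (no wavelet
pair, a single square-window attention), used for the ablation baseline.

``CSMBlock`` — cross-scale fusion: all four stage outputs are resized to
the coarsest grid, concatenated channel-wise, flattened row-major to a
token sequence, passed through a bidirectional selective-scan block, and
the channels corresponding to the coarsest stage are added back to it
residually.
"""

from __future__ import annotations

import numpy as np

from . import nn
from . import tensor as T
from .attention import AttentionSpec, WindowMSA
from .ssm import BiMamba
from .tensor import Tensor
from .wavelet import SubbandSet, haar_dwt2d, haar_idwt2d


class FGTBlock(nn.Module):
    def __init__(self, channels: int, height: int, width: int,
                 specs: dict, ffn_ratio: float = 4.0,
                 rng: np.random.Generator | None = None,
                 literal_ffn_residual: bool = False,
                 zero_init_branches: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        for name in ("A", "H", "V", "D"):
            if specs[name].heads and channels % specs[name].heads:
                raise ValueError(f"channels {channels} not divisible by heads "
                                 f"of branch {name}")
        self.channels = channels
        self.height, self.width = height, width
        self.literal_ffn_residual = literal_ffn_residual
        sh, sw = -(-height // 2), -(-width // 2)  # subband extents (ceil)
        self.norm1 = nn.LayerNorm(channels)
        self.attn_A = WindowMSA(channels, specs["A"], sh, sw, rng,
                                zero_init_proj=zero_init_branches)
        self.attn_H = WindowMSA(channels, specs["H"], sh, sw, rng,
                                zero_init_proj=zero_init_branches)
        self.attn_V = WindowMSA(channels, specs["V"], sh, sw, rng,
                                zero_init_proj=zero_init_branches)
        self.attn_D = WindowMSA(channels, specs["D"], sh, sw, rng,
                                zero_init_proj=zero_init_branches)
        self.norm2 = nn.LayerNorm(channels)
        self.ffn = nn.FeedForward(channels, ffn_ratio, rng,
                                  zero_init_out=zero_init_branches)

    def forward(self, x: Tensor) -> Tensor:
        x = T.astensor(x)
        if x.shape[-1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, "
                             f"got {x.shape[-1]}")
        sb = haar_dwt2d(self.norm1(x))
        fused = haar_idwt2d(SubbandSet(
            self.attn_A(sb.A), self.attn_H(sb.H),
            self.attn_V(sb.V), self.attn_D(sb.D), sb.pad_spec))
        if self.literal_ffn_residual:
            # the printed form: the FFN output *is* the block output
            return self.ffn(self.norm2(fused + x))
        y = fused + x
        return y + self.ffn(self.norm2(y))


class SwinBlock(nn.Module):
    """Standard pre-norm windowed transformer block (spatial baseline)."""

    def __init__(self, channels: int, height: int, width: int,
                 spec: AttentionSpec, ffn_ratio: float = 4.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.norm1 = nn.LayerNorm(channels)
        self.attn = WindowMSA(channels, spec, height, width, rng)
        self.norm2 = nn.LayerNorm(channels)
        self.ffn = nn.FeedForward(channels, ffn_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = T.astensor(x)
        x = x + self.attn(self.norm1(x))
        return x + self.ffn(self.norm2(x))


class PatchEmbed(nn.Module):
    """Non-overlapping P x P patches, linearly projected and normalized."""

    def __init__(self, patch_size: int, in_channels: int, embed_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.patch_size = patch_size
        self.in_channels = in_channels
        self.proj = nn.Linear(patch_size * patch_size * in_channels,
                              embed_dim, rng=rng)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        x = T.astensor(x)
        b, h, w, c = x.shape
        p = self.patch_size
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} image channels, "
                             f"got {c}")
        if h % p or w % p:
            raise ValueError(f"image size {h}x{w} not divisible by patch "
                             f"size {p}")
        x = x.reshape(b, h // p, p, w // p, p, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // p, w // p, p * p * c)
        return self.norm(self.proj(x))


class PatchMerging(nn.Module):
    """2x2 neighborhood concatenation + linear 4C -> 2C (halves resolution,
    doubles channel depth)."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.norm = nn.LayerNorm(4 * channels)
        self.reduction = nn.Linear(4 * channels, 2 * channels, bias=False,
                                   rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"patch merging needs even extents, got {h}x{w}")
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.reduction(self.norm(x))


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """(n_out, n_in) interpolation matrix, half-pixel-center convention."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    m[np.arange(n_out), i0] += 1.0 - frac
    m[np.arange(n_out), i1] += frac
    return m


def bilinear_resize(x: Tensor, out_hw: tuple) -> Tensor:
    """Differentiable bilinear resize of a (B, H, W, C) map."""
    x = T.astensor(x)
    b, h, w, c = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    mh = Tensor(_bilinear_matrix(oh, h).T)   # (h, oh)
    mw = Tensor(_bilinear_matrix(ow, w).T)   # (w, ow)
    y = x.transpose(0, 2, 3, 1) @ mh         # (b, w, c, oh)
    y = y.transpose(0, 3, 2, 1) @ mw         # (b, oh, c, ow)
    return y.transpose(0, 1, 3, 2)           # (b, oh, ow, c)


class StridedDownsample(nn.Module):
    """Learnable factor-f downsample: f x f patch concat + linear, the
    strided-convolution alternative to bilinear resizing."""

    def __init__(self, channels: int, factor: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.factor = factor
        self.proj = (nn.Linear(factor * factor * channels, channels, rng=rng)
                     if factor > 1 else None)

    def forward(self, x: Tensor) -> Tensor:
        f = self.factor
        if f == 1:
            return x
        b, h, w, c = x.shape
        x = x.reshape(b, h // f, f, w // f, f, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // f, w // f, f * f * c)
        return self.proj(x)


class CSMBlock(nn.Module):
    def __init__(self, channels: tuple, target_hw: tuple,
                 state_dim: int = 16, expansion: float = 2.0,
                 conv_width: int = 4, downsample: str = "bilinear",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if downsample not in ("bilinear", "strided"):
            raise ValueError(f"unknown downsample mode {downsample!r}")
        rng = rng or np.random.default_rng(0)
        self.channels = tuple(channels)
        self.target_hw = tuple(target_hw)
        self.total = int(sum(channels))
        self.downsample = downsample
        if downsample == "strided":
            self.reducers = nn.ModuleList(
                [StridedDownsample(ci, 2 ** (len(channels) - 1 - i), rng=rng)
                 for i, ci in enumerate(channels)])
        self.mamba = BiMamba(self.total, state_dim=state_dim,
                             expansion=expansion, conv_width=conv_width,
                             rng=rng)

    def forward(self, features: list) -> Tensor:
        if len(features) != len(self.channels):
            raise ValueError(f"expected {len(self.channels)} stage outputs")
        th, tw = self.target_hw
        nstage = len(features)
        for i, f in enumerate(features):
            factor = 2 ** (nstage - 1 - i)
            b, h, w, c = f.shape
            if c != self.channels[i]:
                raise ValueError(f"stage {i + 1}: expected {self.channels[i]} "
                                 f"channels, got {c}")
            if (h, w) != (th * factor, tw * factor):
                raise ValueError(
                    f"stage {i + 1}: expected resolution "
                    f"{th * factor}x{tw * factor}, got {h}x{w}")
        if self.downsample == "bilinear":
            aligned = [bilinear_resize(f, self.target_hw) for f in features]
        else:
            aligned = [red(f) for red, f in zip(self.reducers, features)]
        fcat = T.concat(aligned, axis=-1)                     # (B, th, tw, D)
        b = fcat.shape[0]
        z = fcat.reshape(b, th * tw, self.total)              # row-major
        ctx = self.mamba(z).reshape(b, th, tw, self.total)
        c4 = self.channels[-1]
        return features[-1] + ctx[..., self.total - c4:]
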