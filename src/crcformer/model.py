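"""Full network assembly.

Patch embedding -> four stages of frequency-aware transformer blocks with
patch merging between stages (halving resolution, doubling channels) ->
optional cross-scale state-space fusion over the four stage outputs ->
global average pooling -> linear classification head.

Ablation switches: ``use_fgt=False`` swaps every frequency-aware block for
a plain spatial windowed-attention block; ``use_csm=False`` removes the
cross-scale fusion.  The four combinations reproduce the baseline /
+CSM / +FGT / full study arms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from . import tensor as T
from .attention import AttentionSpec
from .blocks import CSMBlock, FGTBlock, PatchEmbed, PatchMerging, SwinBlock
from .tensor import Tensor

N_STAGES = 4


@dataclass
class ModelConfig:
    image_size: int = 224
    patch_size: int = 4
    in_channels: int = 3
    num_classes: int = 4
    base_channels: int = 96          # stage widths double: C, 2C, 4C, 8C
    depths: tuple = (2, 2, 6, 2)
    heads: tuple = (3, 6, 12, 24)
    window_big: int = 8              # WB square side
    window_small: int = 2            # WS square side
    stripe: int = 2                  # SH/SV stripe thickness
    swin_window: int = 8             # window of the plain baseline block
    ffn_ratio: float = 4.0
    use_fgt: bool = True
    use_csm: bool = True
    ssm_state: int = 16
    ssm_expansion: float = 2.0
    ssm_conv: int = 4
    downsample: str = "bilinear"
    literal_ffn_residual: bool = False

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError(f"image size {self.image_size} not divisible by "
                             f"patch size {self.patch_size}")
        grid = self.image_size // self.patch_size
        if grid % 2 ** (N_STAGES - 1):
            raise ValueError(f"patch grid {grid} must be divisible by "
                             f"{2 ** (N_STAGES - 1)} for {N_STAGES} stages")
        if len(self.depths) != N_STAGES or len(self.heads) != N_STAGES:
            raise ValueError("depths and heads must have four entries")
        if any(d < 1 for d in self.depths):
            raise ValueError("stage depths must be >= 1")
        for i, h in enumerate(self.heads):
            if (self.base_channels * 2 ** i) % h:
                raise ValueError(f"stage {i + 1} channels not divisible by "
                                 f"{h} heads")

    @property
    def stage_channels(self) -> tuple:
        return tuple(self.base_channels * 2 ** i for i in range(N_STAGES))

    @property
    def stage_resolutions(self) -> tuple:
        grid = self.image_size // self.patch_size
        return tuple(grid // 2 ** i for i in range(N_STAGES))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depths"] = list(d["depths"])
        d["heads"] = list(d["heads"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("depths", "heads"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def tiny_config(**overrides) -> ModelConfig:
    """Desk-scale preset: 64 px input, narrow widths, CPU-friendly."""
    defaults = dict(image_size=64, base_channels=32, depths=(1, 1, 2, 1),
                    heads=(2, 4, 8, 16))
    defaults.update(overrides)
    return ModelConfig(**defaults)


def _fgt_specs(cfg: ModelConfig, stage: int, shifted: bool) -> dict:
    def spec(variant, window):
        return AttentionSpec(variant, window,
                             shift=window // 2 if shifted else 0,
                             heads=cfg.heads[stage])
    return {"A": spec("WB", cfg.window_big),
            "H": spec("SH", cfg.stripe),
            "V": spec("SV", cfg.stripe),
            "D": spec("WS", cfg.window_small)}


class CRCFormer(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        chans = cfg.stage_channels
        res = cfg.stage_resolutions
        self.patch_embed = PatchEmbed(cfg.patch_size, cfg.in_channels,
                                      chans[0], rng=rng)
        self.stages = nn.ModuleList()
        self.merges = nn.ModuleList()
        for i in range(N_STAGES):
            blocks = nn.ModuleList()
            for j in range(cfg.depths[i]):
                shifted = j % 2 == 1
                if cfg.use_fgt:
                    blocks.append(FGTBlock(
                        chans[i], res[i], res[i],
                        _fgt_specs(cfg, i, shifted), cfg.ffn_ratio, rng,
                        literal_ffn_residual=cfg.literal_ffn_residual))
                else:
                    w = cfg.swin_window
                    spec = AttentionSpec(
                        "WS", w, shift=w // 2 if shifted else 0,
                        heads=cfg.heads[i])
                    blocks.append(SwinBlock(chans[i], res[i], res[i], spec,
                                            cfg.ffn_ratio, rng))
            self.stages.append(_Stage(blocks))
            if i < N_STAGES - 1:
                self.merges.append(PatchMerging(chans[i], rng=rng))
        if cfg.use_csm:
            self.csm = CSMBlock(chans, (res[-1], res[-1]),
                                state_dim=cfg.ssm_state,
                                expansion=cfg.ssm_expansion,
                                conv_width=cfg.ssm_conv,
                                downsample=cfg.downsample, rng=rng)
        self.norm = nn.LayerNorm(chans[-1])
        self.head = nn.Linear(chans[-1], cfg.num_classes, rng=rng)

    def forward(self, images) -> Tensor:
        x = T.astensor(images)
        if x.ndim != 4 or x.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, {self.cfg.image_size}, {self.cfg.image_size}, "
                f"{self.cfg.in_channels}) images, got shape {x.shape}")
        x = self.patch_embed(x)
        features = []
        for i in range(N_STAGES):
            for blk in self.stages[i].blocks:
                x = blk(x)
            features.append(x)
            if i < N_STAGES - 1:
                x = self.merges[i](x)
        if self.cfg.use_csm:
            x = self.csm(features)
        x = self.norm(x)
        pooled = x.mean(axis=(1, 2))
        return self.head(pooled)

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def predict_proba(self, images) -> np.ndarray:
        """Softmax class probabilities, evaluation mode (no tape)."""
        with T.no_grad():
            logits = self.forward(images)
            return nn.softmax(logits, axis=-1).data


class _Stage(nn.Module):
    """Container so stage block lists participate in parameter discovery."""

    def __init__(self, blocks: nn.ModuleList):
        super().__init__()
        self.blocks = blocks


def build_model(cfg: ModelConfig, seed: int = 0) -> CRCFormer:
    return CRCFormer(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Checkpoints: weights + full config + seed in a single archive
# ---------------------------------------------------------------------------

def save_checkpoint(model: CRCFormer, path):
    meta = json.dumps({"config": model.cfg.to_dict(), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> CRCFormer:
    try:
        with np.load(path) as archive:
            data = {k: archive[k] for k in archive.files}
    except Exception as exc:
        raise ValueError(f"unreadable checkpoint {path}: {exc}") from exc
    if "__meta__" not in data:
        raise ValueError(f"checkpoint {path} is missing its metadata record")
    meta = json.loads(bytes(data.pop("__meta__")).decode())
    model = CRCFormer(ModelConfig.from_dict(meta["config"]),
                      seed=int(meta["seed"]))
    model.load_state_dict(data)
    return model
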