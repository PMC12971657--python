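"""Manifest-driven image dataset with the minimal training transform:
bilinear resize, optional horizontal flip, channel-wise normalization
with the ImageNet statistics."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def normalize(images: np.ndarray) -> np.ndarray:
    """Channel-wise (x - mean) / std on (.., H, W, 3) arrays in [0, 1]."""
    return (images - IMAGENET_MEAN) / IMAGENET_STD


class ImageDataset:
    """Images listed in a ``path,label`` CSV manifest.

    Relative paths resolve against the manifest's directory.
    """

    def __init__(self, manifest, image_size: int = 224, base_dir=None):
        if isinstance(manifest, pd.DataFrame):
            df = manifest.copy()
            base = Path(base_dir) if base_dir else Path(".")
        else:
            manifest = Path(manifest)
            df = pd.read_csv(manifest)
            base = Path(base_dir) if base_dir else manifest.parent
        for col in ("path", "label"):
            if col not in df.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        if len(df) == 0:
            raise ValueError("empty manifest: no images to load")
        self.df = df.reset_index(drop=True)
        self.base = base
        self.image_size = image_size
        self.labels = self.df["label"].to_numpy(dtype=np.int64)

    def __len__(self):
        return len(self.df)

    def check_labels(self, num_classes: int):
        if self.labels.min() < 0 or self.labels.max() >= num_classes:
            raise ValueError(
                f"manifest labels outside [0, {num_classes}): "
                f"found range [{self.labels.min()}, {self.labels.max()}]")

    def load_image(self, idx: int) -> np.ndarray:
        path = Path(self.df.loc[idx, "path"])
        if not path.is_absolute():
            path = self.base / path
        try:
            with Image.open(path) as im:
                im = im.convert("RGB")
                if im.size != (self.image_size, self.image_size):
                    im = im.resize((self.image_size, self.image_size),
                                   Image.BILINEAR)
                arr = np.asarray(im, dtype=np.float32) / 255.0
        except (OSError, ValueError) as exc:
            raise OSError(f"unreadable image {path}: {exc}") from exc
        return arr

    def load_batch(self, indices, flip_mask=None) -> np.ndarray:
        imgs = np.stack([self.load_image(int(i)) for i in indices])
        if flip_mask is not None:
            imgs[flip_mask] = imgs[flip_mask][:, :, ::-1, :]
        return normalize(imgs)

    def batches(self, batch_size: int, rng: np.random.Generator | None = None,
                shuffle: bool = False, flip_prob: float = 0.0):
        """Yield (images, labels) minibatches; flips and order come from
        ``rng`` so a fixed seed reproduces the epoch exactly."""
        order = np.arange(len(self))
        if shuffle:
            if rng is None:
                raise ValueError("shuffle requires an rng")
            order = rng.permutation(order)
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            flip = None
            if flip_prob > 0:
                flip = rng.random(len(idx)) < flip_prob
            yield self.load_batch(idx, flip), self.labels[idx]
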