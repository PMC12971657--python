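"""Seeded synthetic 4-class image fixtures.

The four classes differ by orientation- and frequency-specific texture,
so a single Haar level already separates them — the discriminability
premise the frequency-aware blocks are built on:

* class 0 — smooth low-frequency blobs (Gaussian-filtered noise; energy
  concentrates in the approximation subband),
* class 1 — horizontal stripes (rows constant; detail energy concentrates
  in the vertical-frequency subband V),
* class 2 — vertical stripes (columns constant; detail energy in H),
* class 3 — high-frequency diagonal checkerboard (detail energy in D).

Per-image period/amplitude/phase jitter and additive Gaussian pixel noise
keep the task non-degenerate.  Generation is fully deterministic under the
spec seed: the same spec writes byte-identical PNGs and manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

N_CLASSES = 4
CLASS_NAMES = ("smooth", "hstripe", "vstripe", "checker")


@dataclass
class SynthSpec:
    n_per_class: int = 50
    image_size: int = 64
    noise_sd: float = 0.05
    stripe_period: float = 4.0
    blob_scale: float = 6.0
    checker_period: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _smooth(rng: np.random.Generator, s: int, spec: SynthSpec) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal((s, s)), spec.blob_scale)
    sd = field.std() or 1.0
    return 0.5 + 0.25 * field / sd


def _stripes(rng: np.random.Generator, s: int, spec: SynthSpec,
             horizontal: bool) -> np.ndarray:
    # keep the period short relative to the 2-sample Haar support so the
    # stripe energy stays in the detail bands
    period = spec.stripe_period * rng.uniform(0.6, 1.1)
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.25, 0.4)
    wave = amp * np.sin(2 * np.pi * np.arange(s) / period + phase) + 0.5
    return np.tile(wave[:, None], (1, s)) if horizontal \
        else np.tile(wave[None, :], (s, 1))


def _checker(rng: np.random.Generator, s: int, spec: SynthSpec) -> np.ndarray:
    half = max(1, spec.checker_period // 2)
    yy, xx = np.meshgrid(np.arange(s) // half, np.arange(s) // half,
                         indexing="ij")
    pattern = np.where((xx + yy) % 2 == 0, 1.0, -1.0)
    if rng.random() < 0.5:
        pattern = -pattern
    amp = rng.uniform(0.25, 0.4)
    return 0.5 + amp * pattern


def make_image(label: int, rng: np.random.Generator,
               spec: SynthSpec) -> np.ndarray:
    """One (S, S, 3) float image in [0, 1] for the given class."""
    s = spec.image_size
    if label == 0:
        img = _smooth(rng, s, spec)
    elif label == 1:
        img = _stripes(rng, s, spec, horizontal=True)
    elif label == 2:
        img = _stripes(rng, s, spec, horizontal=False)
    elif label == 3:
        img = _checker(rng, s, spec)
    else:
        raise ValueError(f"unknown class {label}")
    if spec.noise_sd:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return np.repeat(img[:, :, None], 3, axis=2)


def generate(spec: SynthSpec, out_dir) -> Path:
    """Write the dataset (per-class PNG subdirectories + CSV manifest);
    returns the manifest path."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label in range(N_CLASSES):
        cls_dir = out_dir / f"class_{label}_{CLASS_NAMES[label]}"
        cls_dir.mkdir(exist_ok=True)
        for i in range(spec.n_per_class):
            img = make_image(label, rng, spec)
            u8 = np.round(img * 255).astype(np.uint8)
            rel = f"{cls_dir.name}/img_{i:04d}.png"
            Image.fromarray(u8).save(out_dir / rel)
            rows.append({"path": rel, "label": label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out_dir / "synth_spec.txt", "w") as fh:
        for key, val in dataclasses.asdict(spec).items():
            fh.write(f"{key}={val}\n")
    return manifest


def split(manifest, train_frac: float, seed: int = 0):
    """Stratified disjoint train/test split of a manifest.

    ``manifest`` may be a DataFrame or a CSV path; returns
    ``(train_df, test_df)`` whose union is the input.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    df = manifest if isinstance(manifest, pd.DataFrame) \
        else pd.read_csv(manifest)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for label, group in df.groupby("label", sort=True):
        if len(group) < 2:
            raise ValueError(f"class {label} has fewer than 2 images; "
                             "cannot split")
        order = rng.permutation(len(group))
        n_train = int(round(train_frac * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        train_parts.append(group.iloc[order[:n_train]])
        test_parts.append(group.iloc[order[n_train:]])
    train_df = pd.concat(train_parts).sort_index().reset_index(drop=True)
    test_df = pd.concat(test_parts).sort_index().reset_index(drop=True)
    return train_df, test_df
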