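"""Training and evaluation engine.

Protocol defaults follow the study setup: resize to 224, random
horizontal flip + ImageNet channel normalization as the only
augmentation, Adam at an initial learning rate of 1e-4 decayed by cosine
annealing without restarts (period ``t_max`` = 10 epochs), 300 epochs,
batch size 32, and results averaged over three independent seeds.

The cosine schedule completes its half-period at ``t_max``; past that
point it is held at ``lr_floor`` (1e-6 by default so late training still
moves; set it to 0 for the literal formula, or ``stretch_schedule=True``
to stretch the period over the whole run).
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .data import ImageDataset
from .metrics import MetricsReport, evaluate
from .model import CRCFormer, ModelConfig, load_checkpoint, save_checkpoint
from .optim import Adam
from .tensor import no_grad


@dataclass
class TrainConfig:
    image_size: int = 224
    flip_prob: float = 0.5
    lr0: float = 1e-4
    lr_floor: float = 1e-6
    t_max: int = 10
    stretch_schedule: bool = False
    epochs: int = 300
    batch_size: int = 32
    seeds: tuple = (0, 1, 2)
    eval_batch_size: int = 64

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(d["seeds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "seeds" in d:
            d["seeds"] = tuple(d["seeds"])
        return cls(**d)


def lr_schedule(epoch: float, cfg: TrainConfig) -> float:
    """Cosine annealing without restarts, held at ``lr_floor`` after the
    period ends."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    period = cfg.epochs if cfg.stretch_schedule else cfg.t_max
    e = min(float(epoch), float(period))
    lr = 0.5 * cfg.lr0 * (1.0 + np.cos(np.pi * e / period))
    return float(max(lr, cfg.lr_floor))


@dataclass
class EpochLog:
    seed: int
    epoch: int
    train_loss: float
    lr: float
    eval_metrics: dict | None = None


@dataclass
class RunRecord:
    """Per-epoch logs, per-seed final reports, and the seed-averaged
    summary (arithmetic mean of the per-seed metric values)."""

    epochs: list = field(default_factory=list)
    final_reports: dict = field(default_factory=dict)
    checkpoints: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def finalize(self):
        if not self.final_reports:
            return
        keys = next(iter(self.final_reports.values())).to_dict().keys()
        self.summary = {
            k: float(np.mean([r.to_dict()[k]
                              for r in self.final_reports.values()]))
            for k in keys}


def _predict_probs(model: CRCFormer, dataset: ImageDataset,
                   batch_size: int) -> np.ndarray:
    probs = []
    for images, _ in dataset.batches(batch_size):
        probs.append(model.predict_proba(images))
    return np.concatenate(probs, axis=0)


def evaluate_model(model: CRCFormer, dataset: ImageDataset,
                   batch_size: int = 64) -> MetricsReport:
    dataset.check_labels(model.cfg.num_classes)
    probs = _predict_probs(model, dataset, batch_size)
    return evaluate(probs, dataset.labels)


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, manifest,
          eval_manifest=None, out_dir=None, log=print) -> RunRecord:
    """Run the full protocol: one training per seed, per-epoch logging,
    best-accuracy checkpointing, seed-averaged summary."""
    train_ds = ImageDataset(manifest, image_size=train_cfg.image_size)
    train_ds.check_labels(model_cfg.num_classes)
    eval_ds = (ImageDataset(eval_manifest, image_size=train_cfg.image_size)
               if eval_manifest is not None else None)
    if eval_ds is not None:
        eval_ds.check_labels(model_cfg.num_classes)
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    record = RunRecord()
    log_fh = open(out_dir / "train.log", "w") if out_dir else None

    def emit(line):
        if log:
            log(line)
        if log_fh:
            log_fh.write(line + "\n")
            log_fh.flush()

    try:
        for seed in train_cfg.seeds:
            rng = np.random.default_rng(seed)
            model = CRCFormer(model_cfg, seed=seed)
            opt = Adam(model.parameters(), lr=train_cfg.lr0)
            best_acc = -1.0
            t0 = time.time()
            for epoch in range(train_cfg.epochs):
                lr = lr_schedule(epoch, train_cfg)
                opt.lr = lr
                losses = []
                for step, (images, labels) in enumerate(train_ds.batches(
                        train_cfg.batch_size, rng=rng, shuffle=True,
                        flip_prob=train_cfg.flip_prob)):
                    logits = model(images)
                    loss = nn.cross_entropy(logits, labels)
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    losses.append(float(loss.data))
                    emit(f"seed={seed} epoch={epoch} step={step} "
                         f"loss={losses[-1]:.4f} lr={lr:.2e}")
                entry = EpochLog(seed=seed, epoch=epoch,
                                 train_loss=float(np.mean(losses)), lr=lr)
                if eval_ds is not None:
                    report = evaluate_model(model, eval_ds,
                                            train_cfg.eval_batch_size)
                    entry.eval_metrics = report.to_dict()
                    if report.accuracy > best_acc:
                        best_acc = report.accuracy
                        record.final_reports[seed] = report
                        if out_dir:
                            ckpt = out_dir / f"seed{seed}_best.npz"
                            save_checkpoint(model, ckpt)
                            record.checkpoints[seed] = str(ckpt)
                record.epochs.append(entry)
            if eval_ds is None:
                report = evaluate_model(model, train_ds,
                                        train_cfg.eval_batch_size)
                record.final_reports[seed] = report
                if out_dir:
                    ckpt = out_dir / f"seed{seed}_best.npz"
                    save_checkpoint(model, ckpt)
                    record.checkpoints[seed] = str(ckpt)
            emit(f"seed={seed} done in {time.time() - t0:.1f}s "
                 f"final_acc={record.final_reports[seed].accuracy:.4f}")
    finally:
        if log_fh:
            log_fh.close()
    record.finalize()
    if out_dir:
        with open(out_dir / "summary.txt", "w") as fh:
            for key, val in record.summary.items():
                fh.write(f"{key}\t{val:.6f}\n")
    return record


def evaluate_cmd(checkpoint, manifest, out_dir=None,
                 batch_size: int = 64) -> MetricsReport:
    """Deterministic evaluation of a checkpoint against a manifest."""
    model = load_checkpoint(checkpoint)
    dataset = ImageDataset(manifest, image_size=model.cfg.image_size)
    report = evaluate_model(model, dataset, batch_size)
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.save(out_dir / "metrics.txt")
        report.save_roc_csv(out_dir / "roc")
    return report


def predict_images(checkpoint, image_dir, batch_size: int = 64):
    """Class probabilities for every PNG/JPEG/TIFF under ``image_dir``;
    returns (paths, probability matrix)."""
    import pandas as pd
    model = load_checkpoint(checkpoint)
    exts = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
    paths = sorted(p for p in Path(image_dir).rglob("*")
                   if p.suffix.lower() in exts)
    if not paths:
        raise ValueError(f"no images found under {image_dir}")
    df = pd.DataFrame({"path": [str(p) for p in paths],
                       "label": [0] * len(paths)})
    dataset = ImageDataset(df, image_size=model.cfg.image_size)
    probs = _predict_probs(model, dataset, batch_size)
    return [str(p) for p in paths], probs


# ---------------------------------------------------------------------------
# Config file I/O: a flat YAML document with `model:` and `train:` sections
# ---------------------------------------------------------------------------

def load_configs(path) -> tuple[ModelConfig, TrainConfig]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    model_cfg = ModelConfig.from_dict(doc.get("model", {}))
    train_cfg = TrainConfig.from_dict(doc.get("train", {}))
    return model_cfg, train_cfg


def save_configs(path, model_cfg: ModelConfig, train_cfg: TrainConfig):
    with open(path, "w") as fh:
        yaml.safe_dump({"model": model_cfg.to_dict(),
                        "train": train_cfg.to_dict()}, fh,
                       default_flow_style=False)
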