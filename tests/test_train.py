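"""Training engine: schedule values, determinism, seed averaging,
checkpoint/eval consistency, and the error contract."""

import numpy as np
import pandas as pd
import pytest

from crcformer.data import IMAGENET_MEAN, IMAGENET_STD, ImageDataset, normalize
from crcformer.model import tiny_config
from crcformer.synth import split
from crcformer.train import (TrainConfig, evaluate_cmd, evaluate_model,
                             load_configs, lr_schedule, save_configs, train)

TINY = dict(base_channels=16, depths=(1, 1, 1, 1), heads=(2, 4, 8, 16))


def _fast_train_cfg(**kw):
    base = dict(image_size=64, lr0=1e-3, epochs=2, batch_size=16,
                seeds=(0,), flip_prob=0.5, t_max=10)
    base.update(kw)
    return TrainConfig(**base)


# -- schedule ---------------------------------------------------------------

def test_lr_schedule_protocol_values():
    cfg = TrainConfig()  # protocol defaults: lr0 1e-4, T_max 10
    assert lr_schedule(0, cfg) == 1e-4
    assert lr_schedule(5, cfg) == pytest.approx(5e-5, rel=1e-12)
    # endpoint: the cosine reaches 0, held at the floor
    assert lr_schedule(10, cfg) == cfg.lr_floor
    assert lr_schedule(200, cfg) == cfg.lr_floor
    literal = TrainConfig(lr_floor=0.0)
    assert lr_schedule(10, literal) == pytest.approx(0.0, abs=1e-20)


def test_lr_schedule_stretched_period():
    cfg = TrainConfig(epochs=100, stretch_schedule=True)
    assert lr_schedule(50, cfg) == pytest.approx(5e-5, rel=1e-12)
    assert lr_schedule(100, cfg) == cfg.lr_floor


def test_lr_schedule_rejects_negative_epoch():
    with pytest.raises(ValueError, match="non-negative"):
        lr_schedule(-1, TrainConfig())


# -- augmentation contract --------------------------------------------------

def test_normalization_uses_imagenet_constants():
    np.testing.assert_allclose(IMAGENET_MEAN, [0.485, 0.456, 0.406],
                               rtol=1e-6)
    np.testing.assert_allclose(IMAGENET_STD, [0.229, 0.224, 0.225],
                               rtol=1e-6)
    x = np.full((1, 2, 2, 3), 0.5, dtype=np.float32)
    expected = np.broadcast_to((0.5 - IMAGENET_MEAN) / IMAGENET_STD, x.shape)
    np.testing.assert_allclose(normalize(x), expected, rtol=1e-6)


def test_batches_without_flip_are_pure_resize_normalize(small_dataset):
    _, manifest = small_dataset
    ds = ImageDataset(manifest, image_size=64)
    imgs, labels = next(ds.batches(8))
    raw = np.stack([ds.load_image(i) for i in range(8)])
    np.testing.assert_allclose(imgs, normalize(raw), atol=1e-6)
    assert np.array_equal(labels, ds.labels[:8])


def test_flip_only_mirrors_images(small_dataset):
    _, manifest = small_dataset
    ds = ImageDataset(manifest, image_size=64)
    rng = np.random.default_rng(0)
    imgs, _ = next(ds.batches(8, rng=rng, flip_prob=1.0))
    raw = np.stack([ds.load_image(i) for i in range(8)])
    np.testing.assert_allclose(imgs, normalize(raw)[:, :, ::-1, :], atol=1e-6)


# -- training behaviour -----------------------------------------------------

@pytest.fixture(scope="module")
def trained(small_dataset, tmp_path_factory):
    """One two-seed training run shared by the consistency tests."""
    _, manifest = small_dataset
    out = tmp_path_factory.mktemp("trainout")
    tr, te = split(manifest, 0.5, seed=1)
    # relative image paths resolve against the manifest's own directory
    tr_path, te_path = manifest.parent / "tr.csv", manifest.parent / "te.csv"
    tr.to_csv(tr_path, index=False)
    te.to_csv(te_path, index=False)
    cfg = tiny_config(**TINY)
    record = train(cfg, _fast_train_cfg(seeds=(0, 1)), tr_path,
                   eval_manifest=te_path, out_dir=out, log=None)
    return record, out, te_path


def test_loss_decreases_early(trained):
    record, _, _ = trained
    losses = [e.train_loss for e in record.epochs if e.seed == 0]
    assert losses[-1] < losses[0]


def test_seed_summary_is_arithmetic_mean(trained):
    record, _, _ = trained
    accs = [r.accuracy for r in record.final_reports.values()]
    assert record.summary["accuracy"] == pytest.approx(float(np.mean(accs)))
    f1s = [r.macro_f1 for r in record.final_reports.values()]
    assert record.summary["macro_f1"] == pytest.approx(float(np.mean(f1s)))


def test_checkpoint_eval_matches_trainer_metrics(trained):
    record, out, te_path = trained
    report = evaluate_cmd(record.checkpoints[0], te_path, out_dir=out / "ev")
    logged = record.final_reports[0]
    assert report.accuracy == pytest.approx(logged.accuracy)
    assert report.macro_f1 == pytest.approx(logged.macro_f1)
    assert (out / "ev" / "metrics.txt").exists()
    assert (out / "ev" / "roc" / "roc_class0.csv").exists()


def test_eval_invariant_to_manifest_order(trained):
    record, out, te_path = trained
    df = pd.read_csv(te_path)
    shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
    sh_path = te_path.parent / "te_shuffled.csv"
    shuffled.to_csv(sh_path, index=False)
    a = evaluate_cmd(record.checkpoints[0], te_path)
    b = evaluate_cmd(record.checkpoints[0], sh_path)
    assert a.accuracy == pytest.approx(b.accuracy)
    assert a.macro_auc == pytest.approx(b.macro_auc)


def test_same_seed_training_is_deterministic(small_dataset, tmp_path):
    _, manifest = small_dataset
    cfg = tiny_config(**TINY)
    tcfg = _fast_train_cfg(epochs=1, flip_prob=0.0)
    r1 = train(cfg, tcfg, manifest, log=None)
    r2 = train(cfg, tcfg, manifest, log=None)
    t1 = [e.train_loss for e in r1.epochs]
    t2 = [e.train_loss for e in r2.epochs]
    assert t1 == t2
    assert r1.final_reports[0].accuracy == r2.final_reports[0].accuracy


# -- error contract ---------------------------------------------------------

def test_empty_manifest_rejected(tmp_path):
    path = tmp_path / "empty.csv"
    pd.DataFrame(columns=["path", "label"]).to_csv(path, index=False)
    with pytest.raises(ValueError, match="empty manifest"):
        train(tiny_config(**TINY), _fast_train_cfg(), path, log=None)


def test_unreadable_image_rejected(tmp_path):
    bad = tmp_path / "broken.png"
    bad.write_bytes(b"not a png")
    path = tmp_path / "m.csv"
    pd.DataFrame({"path": [bad.name], "label": [0]}).to_csv(path, index=False)
    ds = ImageDataset(path, image_size=64)
    with pytest.raises(OSError, match="unreadable"):
        ds.load_image(0)


def test_label_overflow_rejected(tmp_path, small_dataset):
    _, manifest = small_dataset
    df = pd.read_csv(manifest)
    df.loc[0, "label"] = 9
    path = tmp_path / "overflow.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="labels outside"):
        train(tiny_config(**TINY), _fast_train_cfg(), path, log=None)
    # evaluation checks class compatibility too
    model = __import__("crcformer.model", fromlist=["CRCFormer"]) \
        .CRCFormer(tiny_config(**TINY), seed=0)
    ds = ImageDataset(path, image_size=64, base_dir=manifest.parent)
    with pytest.raises(ValueError, match="labels outside"):
        evaluate_model(model, ds)


# -- config files -----------------------------------------------------------

def test_config_yaml_round_trip(tmp_path):
    mcfg = tiny_config(**TINY)
    tcfg = _fast_train_cfg(epochs=7)
    path = tmp_path / "cfg.yaml"
    save_configs(path, mcfg, tcfg)
    m2, t2 = load_configs(path)
    assert m2 == mcfg
    assert t2 == tcfg
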