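"""End-to-end training on the synthetic orientation-texture task.

Generates a small 4-class dataset (smooth / horizontal stripes /
vertical stripes / checkerboard), splits it, trains the desk-scale full
model for three epochs, and prints the held-out metrics.  Takes a minute
or two on a laptop CPU.
"""

import tempfile
from pathlib import Path

from crcformer.model import tiny_config
from crcformer.synth import SynthSpec, generate, split
from crcformer.train import TrainConfig, train

tmp = Path(tempfile.mkdtemp(prefix="crcformer_demo_"))
manifest = generate(SynthSpec(n_per_class=40, image_size=64, seed=0), tmp)
train_df, test_df = split(manifest, 0.75, seed=0)
train_df.to_csv(tmp / "train.csv", index=False)
test_df.to_csv(tmp / "test.csv", index=False)
print(f"dataset: {len(train_df)} train / {len(test_df)} test images in {tmp}")

record = train(
    tiny_config(),
    TrainConfig(image_size=64, lr0=1e-3, epochs=3, batch_size=32,
                seeds=(0,), flip_prob=0.5),
    tmp / "train.csv", eval_manifest=tmp / "test.csv", out_dir=tmp / "run",
    log=None)

report = record.final_reports[0]
print(f"test accuracy  {report.accuracy:.3f}")
print(f"macro F1       {report.macro_f1:.3f}")
print(f"macro AUC      {report.macro_auc:.3f}")
print("confusion matrix (rows = true class):")
print(report.confusion_matrix)
print("A perfect run puts all mass on the diagonal; the four classes are "
      "separable from their wavelet-subband signatures alone.")
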