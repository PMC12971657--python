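"""Single-level Haar decomposition of oriented textures.

Builds three 16x16 test patterns and prints how their energy distributes
over the four subbands (A approximation, H horizontal-frequency detail,
V vertical-frequency detail, D diagonal detail).  Stripes load the detail
band matching their orientation; a checkerboard loads the diagonal band.
"""

import numpy as np

from crcformer.wavelet import subband_energies

patterns = {
    "horizontal stripes": np.resize([1.0, -1.0], 16)[:, None] * np.ones((1, 16)),
    "vertical stripes": np.ones((16, 1)) * np.resize([1.0, -1.0], 16)[None, :],
    "checkerboard": (-1.0) ** (np.add.outer(np.arange(16), np.arange(16))),
}

for name, img in patterns.items():
    e = subband_energies(img)
    total = sum(e.values())
    shares = {k: f"{v / total:5.1%}" for k, v in e.items()}
    print(f"{name:20s} {shares}")

print("\nEach oriented texture concentrates its energy in one detail "
      "subband;\nthis is what lets the per-subband attention branches "
      "specialize.")
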