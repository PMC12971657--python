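"""Window and stripe partitions, and the shifted-mask equivalence.

Partitions an 8x8 token grid with each attention variant, prints the
group structure, and verifies that masked attention on the cyclically
rolled grid equals unmasked attention run independently on every window
of the shifted partition (the property that makes window shifting free
of extra parameters).
"""

import numpy as np

from crcformer.attention import (AttentionSpec, partition,
                                 shifted_equivalence_check)

for variant, window in (("WB", 4), ("WS", 2), ("SH", 2), ("SV", 2)):
    spec = AttentionSpec(variant, window, shift=0, heads=2)
    part = partition(8, 8, spec)
    sizes = sorted({len(g) for g in part.groups})
    print(f"{variant}: {len(part.groups):2d} groups, "
          f"group sizes {sizes}, tile {part.tile}")

x = np.random.default_rng(0).standard_normal((1, 8, 8, 4))
for variant, window, shift in (("WS", 4, 2), ("SH", 2, 1), ("SV", 2, 1)):
    ok = shifted_equivalence_check(x, AttentionSpec(variant, window, shift,
                                                    heads=2))
    print(f"shifted {variant} (window {window}, shift {shift}): "
          f"mask equivalence {'holds' if ok else 'FAILS'}")
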