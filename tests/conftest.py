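import numpy as np
import pytest

from crcformer.synth import SynthSpec, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small generated 4-class fixture shared across the session."""
    root = tmp_path_factory.mktemp("synthdata")
    spec = SynthSpec(n_per_class=12, image_size=64, noise_sd=0.05, seed=42)
    manifest = generate(spec, root)
    return spec, manifest
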