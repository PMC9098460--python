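import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from nucleomech import synthetic as syn  # noqa: E402


@pytest.fixture(scope="session")
def clean_nucleus_scene():
    """One noiseless smooth nucleus rendered with both channels."""
    spec = syn.SyntheticNucleusSpec(center=(80.0, 80.0), semi_axes=(40.0, 30.0),
                                    noise_sd=0.0, psf_sigma=0.0)
    return syn.render_nucleus_image(spec, (160, 160), seed=0)


@pytest.fixture(scope="session")
def noisy_five_nucleus_scene():
    return syn.render_scene(
        5, shape=(512, 512), seed=11,
        base_spec=syn.SyntheticNucleusSpec(noise_sd=100.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
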