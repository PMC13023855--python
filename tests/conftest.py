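import numpy as np
import pytest

from cemprep.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Ten patients at 128 px: enough anatomy for segmentation tests, fast."""
    cfg = PhantomConfig(n_patients=10, image_size=128, seed=7,
                        artifact_rate=0.5, confound_strength=0.5)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
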