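import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from busseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def benign_sample():
    return generate_phantom(PhantomSpec(side=64, seed=11))


@pytest.fixture
def narrow_run_config():
    """A thin-channel run configuration for fast pipeline tests."""
    from busseg.pipeline import RunConfig
    return RunConfig(
        variant="rdau", input_side=64, epochs=2, batch_size=8,
        learning_rate=1e-3, seed=5,
        synthetic=dict(n_train=12, n_val=4, n_test=4),
        encoder_filters=[4, 8, 8, 16, 16, 16],
        decoder_filters=[16, 8, 8, 8, 4],
    )
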