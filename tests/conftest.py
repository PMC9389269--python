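import numpy as np
import pytest

from stressfuse.synth import SynthConfig, gen_sample


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def calm_sample(synth_cfg):
    return gen_sample(synth_cfg, "calm", 0)


@pytest.fixture(scope="session")
def stress_sample(synth_cfg):
    return gen_sample(synth_cfg, "experimental", 1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
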