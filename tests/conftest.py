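import numpy as np
import pytest
from hypothesis import settings

from tmbsim import SampleSpec, SeqNoise, synthesize_sample

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_spec():
    """All five mutation types, zero feature noise."""
    return SampleSpec(n_variants=200,
                      composition=(0.2, 0.2, 0.2, 0.2, 0.2),
                      seq_noise=SeqNoise(scale=0.0),
                      n_background=300,
                      seed=7)


@pytest.fixture
def noise_free_sample(noise_free_spec):
    return synthesize_sample(noise_free_spec)


@pytest.fixture
def noisy_sample():
    return synthesize_sample(SampleSpec(seed=3))
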