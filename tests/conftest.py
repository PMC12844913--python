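import pytest

from striplight import synthetic_data as sd


@pytest.fixture(scope="session")
def exp_small():
    """A short noisy virtual experiment shared by read-only tests."""
    return sd.gen_field(sd.EffectConfig(), seed=7, n_days=6)


@pytest.fixture(scope="session")
def exp_noiseless():
    """A short noise-free experiment (clouds on, measurement noise off)."""
    return sd.gen_field(sd.EffectConfig().noiseless(), seed=3, n_days=5)
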