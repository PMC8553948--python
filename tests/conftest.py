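import pytest

from kinpile import gen_freq_panel


@pytest.fixture(scope="session")
def panel_uniform_2k():
    """Small uniform-spectrum panel shared by fast unit tests."""
    return gen_freq_panel(2_000, spectrum="uniform", seed=101)


@pytest.fixture(scope="session")
def panel_beta_5k():
    """Mid-size beta-spectrum panel for estimator/simulator tests."""
    return gen_freq_panel(5_000, spectrum="beta", seed=202)
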