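import pytest

from sectat.dgscale import load_scale


@pytest.fixture(scope="session")
def scale():
    """The packaged biological insertion scale."""
    return load_scale()


@pytest.fixture(scope="session")
def uniform_scale(scale):
    """Same residue values, flat position profile (hand-sum oracle)."""
    return scale.with_uniform_weights()
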