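import pytest

from bdage.model import Intensities


@pytest.fixture(scope="session")
def unit_intensities() -> Intensities:
    """The intensity pair used throughout the reference experiments."""
    return Intensities(1.0, 1.0)
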