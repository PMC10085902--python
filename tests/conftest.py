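import pytest

from diatomtest import MembraneSpec


@pytest.fixture(scope="session")
def spec() -> MembraneSpec:
    """The published membrane geometry: 10 mm disc, 40 fields across."""
    return MembraneSpec(diameter_mm=10.0, fields_per_diameter=40)
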