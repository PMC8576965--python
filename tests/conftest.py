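import pytest
from hypothesis import settings

# no on-disk example database; property tests are derandomized anyway
settings.register_profile("ap2erf", database=None)
settings.load_profile("ap2erf")

from ap2erf.classify import ReferencePanel
from ap2erf.references import synthetic_reference_panel
from ap2erf.registry import GeneRegistry, packaged_registry


@pytest.fixture(scope="session")
def registry() -> GeneRegistry:
    return packaged_registry()


@pytest.fixture(scope="session")
def panel() -> ReferencePanel:
    return synthetic_reference_panel()
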