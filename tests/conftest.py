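import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mutprofile.datamodel import ThresholdConfig
from mutprofile.signatures import toy_signature_catalog
from mutprofile.simulate import GeneratorConfig, generate_cohort, toy_cds


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()

@pytest.fixture(scope="session")
def catalog():
    return toy_signature_catalog()

@pytest.fixture(scope="session")
def cds():
    return toy_cds()

@pytest.fixture(scope="session")
def small_cohort():
    """A modest deterministic cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_samples=2000), seed=11)
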