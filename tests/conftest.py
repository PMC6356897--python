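import numpy as np
import pytest

from thiolprobe.alkylation_kinetics import AlkylationScheme, CysSite
from thiolprobe.synthetic_data import ExperimentConfig


@pytest.fixture
def default_config() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture
def scheme() -> AlkylationScheme:
    """Two-site scheme with the study's cysteine pKa values."""
    return AlkylationScheme(
        CysSite("CysN", 6.63, 100.0),
        CysSite("CysC", 9.53, 100.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
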