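"""Shared fixtures for the pyrimqsar test suite."""
from __future__ import annotations

import numpy as np
import pytest

from pyrimqsar import blind_validation_compounds, published_model
from pyrimqsar.autocorr import descriptor_pool
from pyrimqsar.synthetic import DEFAULT_PLANTED, generate_library


@pytest.fixture(scope="session")
def blind_compounds():
    """The four blind-validation pyrimidines (compounds 40-43), by number."""
    mols = blind_validation_compounds()
    return {m.name.split("_")[0]: m for m in mols}


@pytest.fixture(scope="session")
def eq1_model():
    return published_model()


@pytest.fixture(scope="session")
def library31():
    """31 synthetic training-set-sized molecules (fixed seed)."""
    return generate_library(31, seed=11)


@pytest.fixture(scope="session")
def pool31(library31):
    """Full descriptor pool over the 31-molecule synthetic library."""
    return descriptor_pool(library31)


@pytest.fixture(scope="session")
def planted_signal(pool31):
    """Noise-free activities of the default planted model on pool31."""
    planted = DEFAULT_PLANTED
    X = pool31[list(planted.descriptor_names)].to_numpy(float)
    return planted.intercept + X @ np.asarray(planted.coefficients)
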