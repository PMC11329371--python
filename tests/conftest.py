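"""Shared fixtures for the test suite."""

import numpy as np
import pytest

from fretfluor import AcquisitionMeta, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def meta():
    return AcquisitionMeta()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
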