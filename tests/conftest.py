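import numpy as np
import pytest
from hypothesis import settings

from audlearn.grids import StimulusGrid

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> StimulusGrid:
    return StimulusGrid.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
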