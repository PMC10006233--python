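import numpy as np
import pytest
from hypothesis import settings

from imcseg import ChannelImage, SimulationConfig

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_channel(data, name="Vimentin"):
    return ChannelImage(name, np.asarray(data, dtype=float))


@pytest.fixture
def small_sim_config():
    """Scaled-down ROI: 128×128 px, 12 cells, otherwise simulator defaults."""
    return SimulationConfig(image_size=(128, 128), n_cells=12)
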