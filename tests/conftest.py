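import numpy as np
import pytest

from gfpstate import STRUCTURE_PRESETS, build_structure


@pytest.fixture(scope="session")
def preset_models():
    """The five exemplar synthetic structures, built once."""
    return {name: build_structure(p) for name, p in STRUCTURE_PRESETS.items()}


@pytest.fixture()
def i_like(preset_models):
    return preset_models["I_like"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
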