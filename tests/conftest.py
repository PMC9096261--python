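import numpy as np
import pytest

import roifuse as rf
from roifuse.phantom import CLASSES


@pytest.fixture(scope="session")
def small_atlas():
    """16^3 grid, 8 regions — fast unit-test parcellation."""
    return rf.make_toy_atlas((16, 16, 16), 8, seed=42)


@pytest.fixture(scope="session")
def full_atlas():
    """32^3 grid, 116 regions — AAL-sized parcellation."""
    return rf.make_toy_atlas((32, 32, 32), 116, seed=0)


@pytest.fixture(scope="session")
def small_effects():
    """Effect spec usable with the 8-region atlas (explicit affected set)."""
    return rf.EffectSpec(affected_rois=frozenset({1, 2, 3}), noise_sd=0.05)


@pytest.fixture
def noiseless_effects():
    return rf.EffectSpec(affected_rois=frozenset({1, 2}), noise_sd=0.0)


def zero_effect_spec(noise_sd=0.1):
    return rf.EffectSpec(
        gm_reduction_per_class={c: 0.0 for c in CLASSES},
        pet_reduction_per_class={c: 0.0 for c in CLASSES},
        noise_sd=noise_sd)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
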