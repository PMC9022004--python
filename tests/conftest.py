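"""Shared fixtures: phantoms at two resolutions and a seeded RNG.

The coarse (4 mm) phantom keeps unit tests fast; the default 2 mm
phantom is reserved for the end-to-end checks that need the study
resolution.
"""

import numpy as np
import pytest

from sctdosim import PhantomSpec, build_phantom, default_npc_spec
from sctdosim.pipeline import StudyConfig, build_reference_structures


def coarse_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(shape=(64, 64, 48), spacing=(4.0, 4.0, 4.0), seed=seed)


@pytest.fixture(scope="session")
def coarse_phantom():
    return build_phantom(coarse_spec(7))


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom(default_npc_spec(0))


@pytest.fixture(scope="session")
def coarse_structures(coarse_phantom):
    return build_reference_structures(coarse_phantom, StudyConfig(seeds=(7,)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
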