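"""Shared fixtures: small synthetic inputs used across the suite.

Everything is generated programmatically and seeded; the heavier digital
reference objects are session-scoped so they are built once.
"""

import numpy as np
import pytest

from renalmdr import (AIF, DROSpec, KineticParams2CFM, RigidMotion, make_dro,
                      population_aif)


@pytest.fixture(scope="session")
def fine_aif():
    """Population AIF at pseudo-continuous 0.1 s resolution, 132 s, 15 s baseline."""
    times = (np.arange(1320) + 0.5) * 0.1
    return population_aif(times, baseline=15.0)


@pytest.fixture(scope="session")
def frame_aif(fine_aif):
    """The same AIF block-averaged to the 1.1 s frame grid."""
    return fine_aif.downsample(11)


@pytest.fixture(scope="session")
def reference_params():
    """Mid-range two-compartment filtration parameters."""
    return KineticParams2CFM(FP=150.0, TP=10.0, FT=50.0, TT=120.0)


@pytest.fixture(scope="session")
def small_dro_still():
    """Motion-free, noise-free 48x48, 40-frame DRO."""
    return make_dro(DROSpec(matrix=(48, 48), n_frames=40, motion=None,
                            cnr=None, seed=7))


@pytest.fixture(scope="session")
def small_dro_rigid():
    """48x48, 40-frame DRO with 4 px rigid sinusoidal motion, noise-free."""
    return make_dro(DROSpec(matrix=(48, 48), n_frames=40,
                            motion=RigidMotion(amplitude=4.0, period=4.0),
                            cnr=None, seed=7))
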