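import numpy as np
import pytest

from anpflow.synthetic import make_phantom_embryo


@pytest.fixture(scope="session")
def phantom():
    """Standard spherical-cap phantom shared across test modules."""
    vol, truth = make_phantom_embryo(radius=100.0,
                                     cap_half_angle=np.pi / 3,
                                     n_cells=140, marker_fraction=0.45,
                                     seed=1, rotation=0.0)
    return vol, truth


@pytest.fixture(scope="session")
def rotated_phantom():
    vol, truth = make_phantom_embryo(radius=100.0,
                                     cap_half_angle=np.pi / 3,
                                     n_cells=140, marker_fraction=0.45,
                                     seed=1, rotation=0.4)
    return vol, truth
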