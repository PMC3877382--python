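import numpy as np
import pytest

from mitodyn.presets import calibrated_transport_preset


def sparse_preset(seed: int = 0, **kw):
    """A small, low-density transport preset for fast recovery tests.

    24 particles on a 150 μm axon keeps crossings rare so detection/linking
    operate in their design regime; cohort mean calibrated to 0.02 μm/s.
    """
    defaults = dict(pixel_size=0.1, axon_length=150.0, n_frames=61,
                    n_particles=24, mobile_fraction=0.5)
    defaults.update(kw)
    n = defaults.pop("n_particles")
    mf = defaults.pop("mobile_fraction")
    return calibrated_transport_preset(
        "sparse_test", n, 0.02, mf, 0.085, 0.02, seed=seed, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
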