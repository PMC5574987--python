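import dataclasses

import numpy as np
import pytest

from relaxaniso.phantom import PhantomSpec, default_schedules


@pytest.fixture(scope="session")
def spec():
    """Default phantom specimen, seed 1."""
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Noise-free phantom (snr = inf disables the Rician channel)."""
    return dataclasses.replace(PhantomSpec(seed=1), snr=np.inf)


@pytest.fixture(scope="session")
def schedules():
    return default_schedules()


@pytest.fixture(scope="session")
def orientation_grid():
    return (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)
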