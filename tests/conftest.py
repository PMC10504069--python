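import numpy as np
import pytest

from ecshear.synth import MonolayerSpec, render_monolayer


@pytest.fixture(scope="session")
def monolayer50():
    """Small rendered field: 50 cells, flow-like defaults."""
    return render_monolayer(MonolayerSpec(seed=5, n_cells=50, shape=(260, 260)))


@pytest.fixture(scope="session")
def monolayer100():
    """Medium rendered field: 100 cells, flow-like defaults."""
    return render_monolayer(MonolayerSpec(seed=6, n_cells=100, shape=(370, 370)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def circular_axial_diff_deg(a, b):
    """Smallest axial (mod 180°) difference between angle arrays."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)
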