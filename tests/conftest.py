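import numpy as np
import pytest

from cflvisc import (
    CFLDevelopment,
    ChannelGeometry,
    FluidSpec,
    GridSpec,
)


@pytest.fixture
def blood():
    """Porcine blood at 5 % hematocrit (plasma carrier)."""
    return FluidSpec.from_mpas(1.38, 1.45, 0.05, label="blood 5%")


@pytest.fixture
def baf():
    """Blood-analog fluid at 5 % particle volume fraction."""
    return FluidSpec.from_mpas(2.85, 5.95, 0.05, label="BAF 5%")


@pytest.fixture
def geom():
    return ChannelGeometry(H_um=150.0, W_um=1200.0, L_um=10_000.0)


@pytest.fixture
def dev():
    """Growth law reaching the 20 µm steady CFL at x* = 1601 µm."""
    return CFLDevelopment(a=0.5, x0_um=1.0, h_ss_um=20.0)


@pytest.fixture
def aligned_grid():
    """1 µm wall-normal bins: CFL edges at 10/20 µm fall on cell edges."""
    return GridSpec(n_h=150, n_x_dev=32, n_x_steady=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20240616)
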