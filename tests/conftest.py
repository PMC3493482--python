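import numpy as np
import pytest

import corticalmaps as cm
from corticalmaps.energetics import ModelParams

#: rescaled bias in the middle of the OD-hexagon stability band
ETA_MID = 0.5477


@pytest.fixture(scope="session")
def grid():
    """Two hexagonal unit cells, fine enough for sub-pixel geometry."""
    return cm.make_grid(192, 128, 2, 1)


@pytest.fixture(scope="session")
def grid_small():
    return cm.make_grid(64, 64, 2, 2)


def params_product(c=1.0, eta=ETA_MID, r_op=0.1, r_od=0.2, kc=1.0):
    return ModelParams(r_op=r_op, r_od=r_od, coupling_kind="product_low",
                       c=c, eta=eta, kc=kc)


def params_gradient(c=3.0, eta=ETA_MID, r_op=0.1, r_od=0.2, kc=1.0):
    return ModelParams(r_op=r_op, r_od=r_od, coupling_kind="gradient_low",
                       c=c, eta=eta, kc=kc)


def bandlimited_field(rng, grid, nmodes=6, complex_field=True, amp=1.0):
    """Random band-limited field for property tests."""
    F = np.zeros((grid.nx, grid.ny), complex)
    F[:nmodes, :nmodes] = (rng.standard_normal((nmodes, nmodes))
                           + 1j * rng.standard_normal((nmodes, nmodes)))
    f = np.fft.ifft2(F) * amp
    return f if complex_field else f.real
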