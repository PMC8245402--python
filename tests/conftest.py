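import numpy as np
import pytest

from tdnirs.forward import (
    LayeredMedium,
    OpticalProperties,
    TimeGrid,
    partial_pathlengths_two_layer,
    td_reflectance_two_layer,
)


@pytest.fixture(scope="session")
def grid():
    return TimeGrid.regular(4096, 0.010)


@pytest.fixture(scope="session")
def norm_props():
    """Healthy-group baseline optical properties at the red wavelength."""
    return OpticalProperties(0.15, 10.0, 1.4)


@pytest.fixture(scope="session")
def hetero_medium():
    """A genuinely two-layer medium (scalp/skull over cortex)."""
    return LayeredMedium(
        OpticalProperties(0.15, 10.0, 1.4),
        OpticalProperties(0.20, 8.0, 1.4),
        0.5,
    )


@pytest.fixture(scope="session")
def hetero_curve(grid, hetero_medium):
    return td_reflectance_two_layer(3.0, grid, hetero_medium)


@pytest.fixture(scope="session")
def hetero_pathlengths(grid, hetero_medium, hetero_curve):
    return partial_pathlengths_two_layer(
        3.0, grid, hetero_medium, base=hetero_curve
    )


@pytest.fixture(scope="session")
def equal_layer_fields(grid):
    """Baseline curve and pathlengths for an equal-layer medium at the
    healthy Table values, shared by the simulation-processing tests."""
    from tdnirs.chromophores import DEFAULT_WAVELENGTHS

    props = {687.0: (0.15, 10.0), 826.0: (0.14, 8.7)}
    out = {}
    for wl in DEFAULT_WAVELENGTHS:
        mu_a, mu_sp = props[wl]
        p = OpticalProperties(mu_a, mu_sp, 1.4)
        med = LayeredMedium(p, p, 0.5)
        r0 = td_reflectance_two_layer(3.0, grid, med)
        lt, lb = partial_pathlengths_two_layer(3.0, grid, med, base=r0)
        out[wl] = (r0, lt, lb)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
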