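import numpy as np
import pytest

from kubofit.params import AxesGrid, KuboComponent, LineShapeParams


@pytest.fixture(scope="session")
def tiny_grid() -> AxesGrid:
    """Small grid for fast unit tests: 8 pump delays, 6 waiting times,
    32 probe points, rotating frame 32 cm^-1 below the band."""
    return AxesGrid.from_time(
        tau1_axis=np.arange(8) * 0.25,
        tw_axis=np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0]),
        n_t3=32, dt3=0.25, omega_rf=2130.0)


@pytest.fixture(scope="session")
def one_kubo_params() -> LineShapeParams:
    return LineShapeParams(
        a01=1.0, a12=1.1, omega01=2162.0, d_omega1=0.0, anh=25.5,
        beta=1.0, inv_t_lt=0.0833, inv_t_hom=0.5,
        kubo=(KuboComponent(delta_sq=12.0, tau=2.5),))


@pytest.fixture(scope="session")
def one_kubo_bounds() -> np.ndarray:
    return np.array([
        [0.2, 5.0], [0.2, 5.0], [2158.0, 2166.0], [-1.0, 1.0],
        [20.0, 30.0], [0.7, 1.6], [0.02, 0.25], [0.1, 1.5],
        [0.5, 40.0], [0.5, 10.0],
    ])
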