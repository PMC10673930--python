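import numpy as np
import pytest

from durnet import design as dg
from durnet import forward as fw


@pytest.fixture(scope="session")
def default_timing() -> dg.TimingConfig:
    return dg.TimingConfig()


@pytest.fixture(scope="session")
def small_timing() -> dg.TimingConfig:
    """Reduced acquisition: 2 durations x 2 orientations, short runs."""
    return dg.TimingConfig(n_runs=4, volumes_per_run=48,
                           s1_durations=(0.2, 0.4), orientations=(36.0, 72.0))


@pytest.fixture(scope="session")
def three_node_params() -> fw.BilinearParams:
    A = np.array([[-0.5, 0.0, 0.0], [0.4, -0.5, 0.0], [0.0, 0.3, -0.5]])
    B = np.zeros((1, 3, 3))
    B[0, 2, 1] = 0.2
    C = np.array([[0.4], [0.0], [0.0]])
    return fw.BilinearParams(A=A, B=B, C=C)


@pytest.fixture(scope="session")
def impulse_inputs():
    """Unit-area impulses every 9 s over a 169-volume run, microtime grid."""
    dt = 1.368 / 16
    n_steps = 169 * 16
    U = fw.build_inputs([np.arange(8.0, 220.0, 9.0)], n_steps, dt)
    return U, dt
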