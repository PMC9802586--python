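import numpy as np
import pytest

from fatvt.geometry import ShellParams, build_shell_grid, compute_uvc
from fatvt.synth import SynthConfig, gen_ventricle_images


@pytest.fixture(scope="session")
def small_shell():
    """Coarse half-ellipsoid shell shared across geometry tests."""
    params = ShellParams(long_axis=60.0, short_axis=48.0, wall_thickness=9.0)
    return build_shell_grid(params, resolution_mm=1.5)


@pytest.fixture(scope="session")
def small_uvc(small_shell):
    return compute_uvc(small_shell)


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def one_heart(synth_config):
    """One synthetic heart: (hu, lge, (ct_truth, mri_truth))."""
    return gen_ventricle_images(synth_config, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
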