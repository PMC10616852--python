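import numpy as np
import pytest

from spectramir.simulator import SimulatorConfig, default_panel
from spectramir.spectra import (fixture_dispersion, fixture_dyes,
                                fixture_filter, rpa_adjust)


@pytest.fixture(scope="session")
def dyes():
    return fixture_dyes()


@pytest.fixture(scope="session")
def emission_filter():
    return fixture_filter()


@pytest.fixture(scope="session")
def dispersion_ref():
    return fixture_dispersion()


@pytest.fixture(scope="session")
def dispersion_177(dispersion_ref):
    return rpa_adjust(dispersion_ref, 177.5)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimulatorConfig()


@pytest.fixture(scope="session")
def panel():
    """The default three-class barcode panel at RPA 177.5."""
    return default_panel()


@pytest.fixture(scope="session")
def small_scene(panel):
    """A small rendered scene with ground truth, shared across tests."""
    from spectramir.scene import SceneConfig, render_scene, sample_ground_truth
    from spectramir.simulator import SimulatorConfig

    cfg = SceneConfig(n_fov=6, fov_shape=(192, 192),
                      counts_per_class={"miR-15b": 25, "miR-155": 25,
                                        "miR-126": 25},
                      min_separation_px=10.0)
    gt = sample_ground_truth(cfg, seed=11)
    stack = render_scene(gt, panel, SimulatorConfig(noise_gaussian_var=4.0),
                         seed=11)
    return gt, stack
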