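import numpy as np
import pytest

from mcvcdose import (ApplicatorModel, SimulationConfig, SourceModel,
                      default_true_curves, example_source_model, make_plan)


@pytest.fixture(scope="session")
def source():
    return example_source_model()


@pytest.fixture(scope="session")
def flat_source():
    """Source with g ≡ 1 and F ≡ 1: dose rate reduces to Sk·Λ·G/G0."""
    r = np.array([0.1, 1.0, 10.0])
    th = np.array([0.0, 90.0, 180.0])
    return SourceModel(air_kerma_strength=40800.0, dose_rate_constant=1.109,
                       active_length_mm=3.6,
                       radial_r_cm=r, radial_g=np.ones(3),
                       aniso_r_cm=r, aniso_theta_deg=th,
                       aniso_F=np.ones((3, 3)), name="flat")


@pytest.fixture(scope="session")
def applicator():
    return ApplicatorModel()


@pytest.fixture(scope="session")
def central_plan(source, applicator):
    return make_plan(source, applicator, "central")


@pytest.fixture(scope="session")
def peripheral_plan(source, applicator):
    return make_plan(source, applicator, "peripheral")


@pytest.fixture(scope="session")
def true_curves():
    return default_true_curves()


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(pv_noise_rel=0.0, thickness_amplitude=0.0, seed=11)
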