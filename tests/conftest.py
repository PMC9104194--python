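import numpy as np
import pytest

from maglevlab.physics import Analyte, MagnetConfig, ParamagneticMedium
from maglevlab.simulate import (
    OpticsConfig,
    ParticlePopulation,
    render_frames,
    simulate_trajectories,
)


def single_particle(z0, density, radius=1.0e-5):
    """One-particle population at a given height and density."""
    return ParticlePopulation(
        densities=[density],
        radii=[radius],
        susceptibilities=[-9.0e-6],
        initial_positions=[z0],
        seed=0,
    )


@pytest.fixture(scope="session")
def magnet_config():
    return MagnetConfig()


@pytest.fixture(scope="session")
def medium():
    return ParamagneticMedium()


@pytest.fixture(scope="session")
def levitating_analyte(medium):
    # density slightly above the medium: levitates below the midplane
    return Analyte(density_rho_s=medium.density_rho_m + 10.0)


@pytest.fixture
def rng():
    # function-scoped: draws are independent of test execution order
    return np.random.default_rng(20260903)


@pytest.fixture(scope="session")
def quiet_optics():
    return OpticsConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def bimodal_population(magnet_config):
    return ParticlePopulation.from_mixture(
        n_particles=200,
        density_mixture=[(1350.0, 30.0, 0.7), (1062.0, 4.0, 0.3)],
        config=magnet_config,
        seed=11,
    )


@pytest.fixture(scope="session")
def bimodal_trajectory(bimodal_population, medium, magnet_config):
    return simulate_trajectories(
        bimodal_population, medium, magnet_config, duration=1200.0, dt=2.0
    )


@pytest.fixture(scope="session")
def rendered_series(bimodal_trajectory):
    return render_frames(bimodal_trajectory, OpticsConfig(), seed=11)
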