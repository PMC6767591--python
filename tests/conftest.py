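import numpy as np
import pytest

import fluolung as fl


@pytest.fixture(scope="session")
def relax():
    return fl.RelaxationParams()


@pytest.fixture(scope="session")
def hardware():
    return fl.default_hardware()


@pytest.fixture(scope="session")
def geometry():
    return fl.AcquisitionGeometry()


@pytest.fixture(scope="session")
def phantom():
    """One seeded study phantom with two ventilation defects."""
    return fl.make_lung_phantom(
        matrix=(64, 32, 25),
        fov=(400.0, 320.0, 250.0),
        defect_spec=fl.DefectSpec(count=2, radius_mm=20.0, seed=3),
        seed=1,
    )


@pytest.fixture(scope="session")
def noisy_study(phantom):
    """Phantom acquisition calibrated to the cohort-mean SNR regime (~11.7).

    Returns (phantom, sigma, full k-space, fully sampled reconstruction).
    Session-scoped: the calibration and simulation are shared by recon,
    metrics and acceptance tests.
    """
    sigma = fl.calibrate_noise_for_snr(phantom, 11.7, seed=5, nsa=4)
    ksp = fl.simulate_kspace(phantom, sigma, seed=5, nsa=4)
    full = fl.ifft_reconstruct(ksp)
    return phantom, sigma, ksp, full


@pytest.fixture(scope="session")
def pattern_18():
    return fl.poisson_disc_pattern(32, 25, 1.8, seed=11)


@pytest.fixture()
def rng():
    # function-scoped so draws are reproducible regardless of test order
    return np.random.default_rng(2024)
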