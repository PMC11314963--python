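import numpy as np
import pytest

import volsense as vs


@pytest.fixture(scope="session")
def schedule():
    return vs.PhaseSchedule()  # 100/200/500 s at 1 Hz


@pytest.fixture(scope="session")
def array():
    return vs.default_sensor_array()


@pytest.fixture
def quiet_noise():
    return vs.NoiseModel(multiplicative_sigma=0.0, drift_per_s=0.0, seed=0)


@pytest.fixture(scope="session")
def small_dataset(schedule, array):
    """120-cycle cooked-diet campaign (4 classes x 6 samples x 5 replicates)."""
    crm = cooked_submatrix(vs.default_response_matrix(), separation=1.0)
    design = vs.ExperimentDesign(n_samples=24, enose_replicates=5)
    noise = vs.NoiseModel(seed=7)
    cycles, labels = vs.simulate_dataset(design, crm, vs.default_sensor_array(),
                                         vs.PhaseSchedule(), noise)
    X, y = vs.build_matrix(cycles)
    return cycles, X, y


def cooked_submatrix(crm, separation):
    """Restrict a response matrix to the four cooked classes."""
    idx = [i for i, c in enumerate(crm.classes) if c.startswith("CK")]
    return vs.ClassResponseMatrix(
        tuple(crm.classes[i] for i in idx), crm.amplitudes[:, idx], separation
    )


@pytest.fixture(scope="session")
def gaussian_4class():
    """Well-conditioned 4-class Gaussian data for LDA cross-checks."""
    rng = np.random.default_rng(42)
    p = 5
    A = rng.normal(size=(p, p))
    cov = A @ A.T / p + np.eye(p)
    mus = rng.normal(scale=1.5, size=(4, p))
    X = np.vstack([rng.multivariate_normal(mus[i], cov, 100) for i in range(4)])
    y = np.repeat([f"c{i}" for i in range(4)], 100)
    return X, y
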