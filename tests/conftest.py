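import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mbarwtp as m
from mbarwtp.toy import gaussian_bump

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_window_samples():
    """Two overlapping harmonic windows on a separable harmonic potential.

    The biased partition functions are analytic up to quadrature, so the
    MBAR free-energy difference has a deterministic oracle.
    """
    system = m.ToySystem.harmonic(k=(20.0, 20.0), offset=1.5, seed=11)
    windows = [
        m.WindowSpec(0, (-0.2, 0.0), (50.0, 50.0)),
        m.WindowSpec(1, (0.2, 0.0), (50.0, 50.0)),
    ]
    samples = m.sample_windows(system, windows, 5000)
    return system, windows, samples


@pytest.fixture(scope="session")
def two_window_solution(two_window_samples):
    _, _, samples = two_window_samples
    return m.solve_mbar(samples)


@pytest.fixture(scope="session")
def bump_grid_data():
    """5x5 umbrella windows on a harmonic well with a smooth Gaussian-bump
    low->high perturbation; frames strided for near-independence so the
    per-bin delta-method standard errors are meaningful."""
    system = m.ToySystem.harmonic(
        k=(15.0, 15.0),
        offset=gaussian_bump(1.0, (0.0, 0.0), 0.4),
        seed=5,
    )
    windows = m.make_windows((-0.4, 0.4), 0.2, 60.0)
    samples = m.sample_windows(system, windows, 500, stride=10)
    sol = m.solve_mbar(samples)
    grid = m.Grid2D.from_range(-0.4, 0.4, 0.2)
    return system, samples, sol, grid


@pytest.fixture()
def single_window_flat():
    """One window with zero force constants: all biases vanish, so every
    frame must carry the same unbiased weight."""
    rng = np.random.default_rng(3)
    windows = [m.WindowSpec(0, (0.0, 0.0), (0.0, 0.0))]
    n = 600
    rc = rng.normal(scale=0.5, size=(n, 2))
    u_low = rng.normal(size=n)
    return m.SampleSet(windows, np.zeros(n, dtype=int), rc, u_low, 298.15)
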