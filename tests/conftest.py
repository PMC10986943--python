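import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """Small default skeleton (300 points/bone) shared across tests."""
    from wingkin.skeleton import default_skeleton
    return default_skeleton(seed=1, n_points=300)


@pytest.fixture(scope="session")
def noiseless_dataset(small_truth):
    from wingkin.skeleton import pose_skeleton
    return pose_skeleton(small_truth, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_dataset(small_truth):
    from wingkin.skeleton import pose_skeleton
    return pose_skeleton(small_truth, noise_sd=0.3, seed=2)


@pytest.fixture(scope="session")
def mech_config():
    from wingkin.mechanism import default_config
    return default_config()


def brute_force_residual(target: np.ndarray, candidate: np.ndarray) -> float:
    """Independent all-pairs oracle for the one-sided mean NN distance."""
    target = np.asarray(target, float)
    candidate = np.asarray(candidate, float)
    total = 0.0
    for x in target:
        best = np.inf
        for y in candidate:
            d = float(np.sqrt(((x - y) ** 2).sum()))
            if d < best:
                best = d
        total += best
    return total / len(target)
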