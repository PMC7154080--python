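import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plimse.pipeline import RunConfig, run_all
from plimse.synthetic import CohortConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_config():
    """A reduced cohort (10 + 10 subjects, full 60-s recordings) with the
    default group contrasts: reduced alpha/beta/gamma coupling and a steeper
    noise spectrum in the AD-like group."""
    return RunConfig(cohort=CohortConfig(n_hc=10, n_ad=10, master_seed=7))


@pytest.fixture(scope="session")
def demo_run(demo_config, tmp_path_factory):
    """One full pipeline run shared by the structure and recovery tests."""
    out = tmp_path_factory.mktemp("demo_run")
    report = run_all(demo_config, out)
    return report


def bh_stepup_oracle(pvals: np.ndarray, q: float) -> np.ndarray:
    """Exhaustive step-up enumeration: largest k with p_(k) <= k q / m."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    if k_star:
        mask[order[:k_star]] = True
    return mask


def brute_force_sampen(x: np.ndarray, m: int, r: float) -> float:
    """Definitional O(T^2) sample entropy: explicit Chebyshev distance matrix
    over all template pairs on the common index range."""
    x = np.asarray(x, dtype=float)
    n_templates = x.size - m

    def count(length: int) -> int:
        windows = np.stack([x[i:i + length] for i in range(n_templates)])
        dist = np.abs(windows[:, None, :] - windows[None, :, :]).max(axis=-1)
        iu = np.triu_indices(n_templates, 1)
        return int((dist[iu] <= r).sum())

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b)) + 0.0
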