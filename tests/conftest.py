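import numpy as np
import pandas as pd
import pytest

from geecr import CaptureHistory, scenario, simulate_population


@pytest.fixture
def small_history():
    """Tiny hand-checkable dataset: 3 individuals, 3 occasions."""
    y = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1]])
    cov = pd.DataFrame({"sex": [1.0, 0.0, 1.0], "weight": [14.0, 15.5, 16.0]})
    return CaptureHistory(y=y, covariates=cov)


@pytest.fixture(scope="session")
def medium_population():
    """One simulated high-capture population reused across tests."""
    return simulate_population(scenario("a", N=400, m=6), np.random.default_rng(1234))


def random_history(rng, n=20, m=5, ncov=2):
    """Random valid CaptureHistory (every row captured at least once)."""
    y = (rng.random((n, m)) < 0.4).astype(int)
    force = rng.integers(0, m, size=n)
    y[np.arange(n), force] = 1
    cov = pd.DataFrame(
        {f"c{k}": np.round(rng.normal(size=n), 6) for k in range(ncov)}
    )
    return CaptureHistory(y=y, covariates=cov)
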