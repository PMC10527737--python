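import numpy as np
import pytest

from cenplam import CensoredDataset, ScenarioConfig, generate_censored_dataset


@pytest.fixture
def toy3():
    """The 3-point worked case: one censored observation in the middle."""
    return CensoredDataset(
        z=[1.0, 2.0, 3.0],
        delta=[1, 0, 1],
        X=np.array([[1.0], [2.0], [3.0]]),
        T=np.array([[0.0], [0.5], [1.0]]),
        is_sorted=True,
    )


@pytest.fixture
def uncensored_ds():
    rng = np.random.default_rng(42)
    n = 40
    X = rng.standard_normal((n, 2))
    T = np.column_stack([np.linspace(0, 1, n), rng.uniform(-2, 2, n)])
    z = X @ [1.0, -0.5] + np.sin(2 * T[:, 1]) + rng.normal(0, 0.5, n)
    return CensoredDataset(z=z, delta=np.ones(n, dtype=int), X=X, T=T)


@pytest.fixture
def censored_ds():
    """Moderately censored n=30 replicate from the simulation design."""
    data, f_true = generate_censored_dataset(
        ScenarioConfig(n=30, cl=0.2, seed=3), seed=3
    )
    return data, f_true
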