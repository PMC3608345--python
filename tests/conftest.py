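import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from anthrocomp import AnthropometricRecord
from anthrocomp.synthetic import default_moments

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def moments():
    """Shared default population moments (latent copula adjustment is cached
    on the instance, so building it once keeps the suite fast)."""
    return default_moments()


@pytest.fixture(scope="session")
def toy_xy():
    """Four-point single-predictor problem with hand-computed PRESS."""
    X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
    Y = pd.DataFrame({"y": [2.0, 1.0, 4.0, 3.0]})
    return X, Y


@pytest.fixture
def worked_example_record():
    """The printed worked example: a 13-year-old boy, PHV given directly."""
    return AnthropometricRecord(
        height=148.3,
        weight=40.0,
        sk_suprailiac=18.7,
        sk_horiz_abdominal=20.0,
        phv=-1.6,
    )


def random_problem(seed, n=None, p=None, m=3):
    """Well-conditioned random regression problem for property tests."""
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(20, 61))
    p = p or int(rng.integers(1, 7))
    X = pd.DataFrame(
        rng.normal(size=(n, p)) + rng.normal(scale=0.5, size=(1, p)),
        columns=[f"x{j}" for j in range(p)],
    )
    beta = rng.normal(size=(p, m))
    Y = pd.DataFrame(
        X.to_numpy() @ beta + rng.normal(scale=0.7, size=(n, m)),
        columns=[f"y{j}" for j in range(m)],
    )
    return X, Y
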