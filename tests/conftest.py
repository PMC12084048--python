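import numpy as np
import pandas as pd
import pytest

from mosr.expressions import sigmoid
from mosr.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient cohort with default feature structure."""
    return generate_cohort(GeneratorConfig(n_patients=300, seed=7))


def make_planted_problem(seed: int, n_train: int = 1000, n_test: int = 20000,
                         n_noise: int = 3):
    """Binary labels from a planted logit y = 1[sigmoid(3*x1 - 3*x2) > u]."""
    rng = np.random.default_rng(10_000 + seed)
    d = 2 + n_noise
    cols = [f"x{i + 1}" for i in range(d)]
    X = pd.DataFrame(rng.normal(size=(n_train, d)), columns=cols)
    y = (sigmoid((3 * X.x1 - 3 * X.x2).to_numpy()) > rng.random(n_train)).astype(int)
    Xte = pd.DataFrame(rng.normal(size=(n_test, d)), columns=cols)
    yte = (sigmoid((3 * Xte.x1 - 3 * Xte.x2).to_numpy())
           > rng.random(n_test)).astype(int)
    return X, y, Xte, yte
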