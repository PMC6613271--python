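import numpy as np
import pytest

import morbidlca as m


@pytest.fixture(scope="session")
def code_table():
    return m.load_code_table()


@pytest.fixture(scope="session")
def default_cfg():
    return m.default_config()


@pytest.fixture(scope="session")
def small_cohort(default_cfg):
    """A 4000-patient draw from the default six-class generator."""
    return m.generate_cohort(default_cfg, n=4000, seed=77)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return m.prepare_dataset(
        small_cohort.indicators,
        m.ELIXHAUSER_CATEGORIES,
        small_cohort.cohort["age"].to_numpy(),
        small_cohort.cohort["elective"].to_numpy(),
    )


def random_binary_dataset(rng, n, n_vars):
    """A small all-binary CategoricalDataset for oracle tests."""
    values = rng.integers(0, 2, size=(n, n_vars))
    return m.CategoricalDataset(
        tuple(f"v{j}" for j in range(n_vars)),
        np.full(n_vars, 2),
        values,
    )


def random_model(rng, K, n_levels):
    """A random valid LCAModel for oracle tests."""
    pi = rng.dirichlet(np.ones(K))
    rho = [rng.dirichlet(np.ones(C), size=K) for C in n_levels]
    return m.LCAModel(K=K, pi=pi, rho=rho)
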