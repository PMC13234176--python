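import numpy as np
import pandas as pd
import pytest

from fwmrs import BiasSpec, Dataset, PopulationSpec, generate_population, make_split


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_tables(tmp_path):
    """A pair of small CSV files sharing a schema, N carrying an outcome."""
    n = pd.DataFrame({
        "age": [34, 58, 41, 29, 62, 45],
        "sex": ["f", "m", "f", "f", "m", "m"],
        "income": [3.1, 4.5, 2.2, 1.9, 5.0, 3.3],
        "vote": [1, 0, 1, 0, 0, 1],
    })
    r = pd.DataFrame({
        "age": [31, 47, 52, 38, 60],
        "sex": ["m", "f", "m", "f", "f"],
        "income": [2.8, 3.9, 4.1, 2.5, 4.8],
    })
    n_path, r_path = tmp_path / "n.csv", tmp_path / "r.csv"
    n.to_csv(n_path, index=False)
    r.to_csv(r_path, index=False)
    return n_path, r_path


@pytest.fixture(scope="session")
def population():
    """A mixed numeric/categorical population with a logistic outcome."""
    return generate_population(
        PopulationSpec(n_numeric=5, n_categorical=1), n=600, seed=7)


@pytest.fixture(scope="session")
def biased_split(population):
    """One (N, R, T) split with the positive class undersampled in N."""
    return make_split(population, repeat_seed=3, fold=0,
                      bias=BiasSpec(retained_fraction=0.10, random_seed=3))


def matched_pair(n_rows, p=5, seed=0, shift=None):
    """Two i.i.d. Gaussian matrices (optionally location-shifted in N)."""
    rng = np.random.default_rng(seed)
    Xn = rng.standard_normal((n_rows, p))
    Xr = rng.standard_normal((n_rows, p))
    if shift is not None:
        Xn = Xn + np.asarray(shift)
    return Xn, Xr
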