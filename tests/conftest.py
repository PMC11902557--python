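import numpy as np
import pytest

from soyspec.containers import SpectraTable, WavelengthGrid
from soyspec.synthetic import default_config, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic three-class dataset (seed 0) plus ground truth."""
    table, truth = generate_dataset(default_config(seed=0))
    return table, truth


@pytest.fixture
def small_table():
    """A tiny deterministic 6-sample, 4-band two-class table."""
    rng = np.random.default_rng(7)
    X = rng.uniform(0.2, 0.8, size=(6, 4))
    X[:3, 1] += 0.5
    return SpectraTable(X, WavelengthGrid(np.array([400.0, 450.0, 500.0, 550.0])),
                        np.array(["a", "a", "a", "b", "b", "b"]))


def make_recovery_table(seed: int, n_per: int = 30, p: int = 12,
                        bands=(3, 8), shift: float = 0.3):
    """Three classes, two truly discriminative bands, all others pure noise."""
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(np.linspace(400.0, 900.0, p))
    X = rng.normal(0.5, 0.05, size=(3 * n_per, p))
    labels = np.array(["a"] * n_per + ["b"] * n_per + ["c"] * n_per)
    X[:n_per, bands[0]] += shift
    X[n_per:2 * n_per, bands[1]] += shift
    return SpectraTable(X, grid, labels), set(bands)
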