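import numpy as np
import pytest

from mgem.data import fit_boxcox
from mgem.predictor import OraclePredictor
from mgem.synthetic import SyntheticConfig, generate_proteome, make_feature_tables


@pytest.fixture(scope="session")
def small_proteome():
    """A small planted-signal proteome shared across unit tests."""
    cfg = SyntheticConfig(
        n_proteins=80, length_range=(100, 200), n_replicates_max=5, seed=42
    )
    records, truth = generate_proteome(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def transform(small_proteome):
    _, records, _ = small_proteome
    return fit_boxcox([r.median_abundance for r in records])


@pytest.fixture(scope="session")
def oracle(small_proteome, transform):
    _, records, truth = small_proteome
    return OraclePredictor(
        truth, transform, known_sequences={r.sequence for r in records}
    )


@pytest.fixture(scope="session")
def feature_tables(small_proteome):
    _, _, truth = small_proteome
    return make_feature_tables(truth, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
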