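import numpy as np
import pytest

from snpbarcode import GenotypeDataset, reconstruct_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    dataset, _ = reconstruct_fixture()
    return dataset


@pytest.fixture(scope="session")
def fixture_report():
    _, report = reconstruct_fixture()
    return report


@pytest.fixture
def random_dataset():
    """Small random dataset factory for brute-force oracle comparisons."""

    def make(n_cases=40, n_controls=30, n_snps=5, seed=0):
        rng = np.random.default_rng(seed)
        codes = rng.integers(1, 3, size=(n_cases + n_controls, n_snps))
        is_case = np.concatenate([np.ones(n_cases, bool), np.zeros(n_controls, bool)])
        return GenotypeDataset(codes=codes, is_case=is_case)

    return make
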