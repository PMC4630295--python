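import pytest

from phasereg import fixtures
from phasereg.phase_preprocess import preprocess_series


@pytest.fixture(scope="session")
def design():
    return fixtures.single_vein_design()


@pytest.fixture(scope="session")
def single_phantom():
    return fixtures.make_single_vein_phantom(seed=0)


@pytest.fixture(scope="session")
def single_pre(single_phantom):
    return preprocess_series(single_phantom)


@pytest.fixture(scope="session")
def lat_pre_pair():
    """Preprocessed train/test runs of the two-vein laterality phantom."""
    train = preprocess_series(fixtures.make_laterality_phantom(seed=0)).series
    test = preprocess_series(fixtures.make_laterality_phantom(seed=1000)).series
    return train, test


@pytest.fixture(scope="session")
def pr_pair():
    return fixtures.pr_fixture_pair()
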