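import numpy as np
import pytest

from sageprev import load_panel_fixture
from sageprev.sage_io import SageCatalogue, clean_catalogue, normalize


@pytest.fixture(scope="session")
def panel():
    return load_panel_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20121109)


def make_normalized(accession, counts):
    """Raw counts -> cleaned, tpm-normalized catalogue."""
    return normalize(clean_catalogue(SageCatalogue(accession, dict(counts))))


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])
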