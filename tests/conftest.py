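import numpy as np
import pytest

from sirnakit import synthetic_data as syn

BASES = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture(scope="session")
def isoform_gene():
    """A two-isoform gene with brute-forced exclusive-site ground truth."""
    return syn.make_isoform_gene(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
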