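import numpy as np
import pytest

from polclock import refsigs
from polclock.reference import build_reference


@pytest.fixture(scope="session")
def ref_small():
    """100 kb gene-free reference."""
    return build_reference(1, {"chr1": 100_000}, n_genes=0)


@pytest.fixture(scope="session")
def ref_genes():
    """400 kb reference with 40 genes, used by selection/signature tests."""
    return build_reference(3, {"chr1": 400_000}, n_genes=40,
                           gene_length_range=(300, 900))


@pytest.fixture(scope="session")
def sbs_sigs():
    return refsigs.synthetic_sbs_signatures()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
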