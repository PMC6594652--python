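import numpy as np
import pytest

from lsrseq.reference import ReferenceRegion, ReferenceSet
from lsrseq.simulate import default_reference_set


@pytest.fixture(scope="session")
def regions():
    """The packaged desk-scale synthetic reference set."""
    return default_reference_set(0)


@pytest.fixture(scope="session", autouse=True)
def _warm_aligner(regions):
    """Compile the numba kernel once so per-test timings are honest."""
    from lsrseq.align import smith_waterman

    smith_waterman("ACGTACGTACGT", "ACGTACGTACGT")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture()
def tiny_regions():
    """Two small non-repetitive regions for alignment unit tests."""
    rng = np.random.default_rng(7)
    return ReferenceSet(
        [
            ReferenceRegion("D1", random_dna(rng, 400), "donor"),
            ReferenceRegion("A1", random_dna(rng, 400), "acceptor"),
        ]
    )
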