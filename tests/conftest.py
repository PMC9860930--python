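import numpy as np
import pytest

from selconv import io_formats as io


SIX_TAXON_NEWICK = ("(((A:0.08,B:0.08):0.05,(C:0.07,D:0.07):0.06):0.04,"
                    "(E:0.1,F:0.1):0.03);")


@pytest.fixture(scope="session")
def six_taxon_tree() -> io.Tree:
    return io.parse_tree(SIX_TAXON_NEWICK)


@pytest.fixture(scope="session")
def quartet_tree() -> io.Tree:
    return io.parse_tree("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
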