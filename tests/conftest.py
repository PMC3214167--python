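import numpy as np
import pytest

from gauscan.codon_core import get_code
from gauscan.gau_locator import extract_gau_region, find_anchor
from gauscan.synthetic_data import OverlapSpec, make_overlap_cds


@pytest.fixture(scope="session")
def code_std():
    return get_code(1)


@pytest.fixture(scope="session")
def code_vmt():
    return get_code(2)


@pytest.fixture(scope="session")
def code_imt():
    return get_code(5)


@pytest.fixture(scope="session")
def planted_vmt():
    """Vertebrate-mt CDS with 8 planted AGR codons (stops under that code)."""
    gen = make_overlap_cds(OverlapSpec(seed=1, agr_count=8, code_id=2))
    return gen


@pytest.fixture(scope="session")
def planted_vmt_region(planted_vmt, code_vmt):
    hits = find_anchor(planted_vmt.cds, code_vmt)
    return extract_gau_region(planted_vmt.cds, code_vmt, hits[0], parent_id="syn")


@pytest.fixture(scope="session")
def planted_imt():
    """Invertebrate-mt CDS with stops planted in windows ii and iii."""
    return make_overlap_cds(
        OverlapSpec(seed=7, agr_count=11, stops={"ii": [40, 77], "iii": [12]}, code_id=5)
    )


def random_cds(rng: np.random.Generator, n_codons: int, code) -> str:
    """Random internally stop-free CDS with a terminal stop."""
    non_stop = sorted(set(code.table) - code.stops)
    body = [non_stop[i] for i in rng.integers(len(non_stop), size=n_codons - 1)]
    stop = sorted(code.stops)[int(rng.integers(len(code.stops)))]
    return "".join(body) + stop
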