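import numpy as np
import pytest

import porescreen as ps


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_922)


@pytest.fixture(scope="session")
def toy_records():
    return [
        ps.SequenceRecord("chrA", "ACGTACGTGGATCCATCGATCG"),
        ps.SequenceRecord("chrB", "TTTTGGGGCCCCAAAA"),
    ]


@pytest.fixture(scope="session")
def toy_pos_text(toy_records):
    return ps.build_positive_text(toy_records)


@pytest.fixture(scope="session")
def toy_ms_index(toy_pos_text):
    return ps.build_index(toy_pos_text, mode=ps.MODE_MS)


@pytest.fixture(scope="session")
def toy_pml_index(toy_pos_text):
    return ps.build_index(toy_pos_text, mode=ps.MODE_PML)


@pytest.fixture(scope="session")
def small_reference():
    """A 50-kb random reference with its positive/null PML index pair."""
    rng = np.random.default_rng(4242)
    seq = random_dna(rng, 50_000)
    records = [ps.SequenceRecord("ref", seq)]
    pos_text = ps.build_positive_text(records)
    null_text = ps.build_null_text(pos_text)
    pos_index = ps.build_index(pos_text, mode=ps.MODE_PML)
    null_index = ps.build_index(null_text, mode=ps.MODE_PML)
    return records, pos_index, null_index
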