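import pytest

from vasco.core import NucleusGroup
from vasco.synthetic import default_layout, make_entry, make_refdb


@pytest.fixture(scope="session")
def refdb():
    """Direct-mode synthetic reference database, one class per group."""
    return make_refdb(default_layout(), seed=0, mode="direct")


@pytest.fixture(scope="session")
def offset_entry(refdb):
    """Entry with a known +2 ppm aliphatic-carbon offset."""
    return make_entry(refdb, 400, {NucleusGroup.C_ali: 2.0},
                      noise_scale=1.0, seed=3)


@pytest.fixture(scope="session")
def clean_entry(refdb):
    """Zero-offset entry (no correction should be retained)."""
    return make_entry(refdb, 1000, {}, noise_scale=1.0, seed=11)
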