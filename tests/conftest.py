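import pytest

from bcscreen import BarcodePool, ReadLayout, conway_generate

# Fixed synthetic sequences for read-structure tests: a clamp (the spacer
# the RT oligo anchors on) and a stand-in for the 3' UTR tail upstream of
# the barcode.
CLAMP = "TCTAGACTGGTACGTA"
PREFIX = "GGCATCGAAGTCCTGA"


@pytest.fixture(scope="session")
def pool200():
    """First 200 barcodes of default generation (length 12, d_min 4)."""
    return conway_generate(12, 4, stop_after=200)


@pytest.fixture(scope="session")
def pool20():
    return conway_generate(12, 4, stop_after=20)


@pytest.fixture
def dimer_pool():
    return BarcodePool.from_sequences(["AA", "CC", "GG", "TT"], d_min=2)


@pytest.fixture
def layout():
    return ReadLayout(clamp=CLAMP, fixed_prefix=PREFIX)
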