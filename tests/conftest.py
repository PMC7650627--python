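from importlib.resources import files

import pytest

from pexsplice.synthetic_data import SimConfig, generate_locus
from pexsplice.transcript import TranscriptMap


@pytest.fixture(scope="session")
def dmd_like_tmap() -> TranscriptMap:
    """A minus-strand two-exon transcript fragment anchored so that coding
    position 7310 (the first base of the downstream exon) maps to plus-strand
    genomic position 31,792,309 (1-based), as in the dystrophin transcript."""
    return TranscriptMap(
        exons=[(31800000, 31807309), (31792109, 31792309)],
        strand="-",
    )


@pytest.fixture(scope="session")
def locus():
    """One synthetic locus shared by read-only tests."""
    return generate_locus(SimConfig(seed=11))


@pytest.fixture(scope="session")
def curated_catalog_path():
    return str(files("pexsplice").joinpath("data/dmd_pe_catalog_synthetic.tsv"))
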