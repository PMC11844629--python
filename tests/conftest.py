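import numpy as np
import pytest

from epinherit.io_formats import GeneModel
from epinherit.methylation import GenomicInterval, RegionMethylation


@pytest.fixture
def two_gene_models() -> list[GeneModel]:
    """Two genes on opposite strands with two exons each."""
    plus = GeneModel.from_exons("geneA", "chr1", "+",
                                [(10_000, 10_200), (10_300, 10_400)])
    minus = GeneModel.from_exons("geneB", "chr1", "-",
                                 [(30_000, 30_200), (30_300, 30_400)])
    return [plus, minus]


def make_region(counts_t, counts_c, region_id="r1", start=0):
    """RegionMethylation from per-replicate (meth, unmeth) tuples."""
    counts = {}
    groups = {}
    for i, (m, u) in enumerate(counts_t, start=1):
        name = f"exposed_rep{i}"
        counts[name] = (m, u)
        groups[name] = "exposed"
    for i, (m, u) in enumerate(counts_c, start=1):
        name = f"control_rep{i}"
        counts[name] = (m, u)
        groups[name] = "control"
    return RegionMethylation(
        region=GenomicInterval("chr1", start, start + 100),
        region_id=region_id, counts=counts, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
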