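import pytest
from hypothesis import HealthCheck, settings

from bowstrap.formats import Alignment, GeneModel, GeneTable, ReadAlignments

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_genes() -> GeneTable:
    """Three gene models with distinct lengths."""
    return GeneTable(
        [GeneModel("geneA", 1000), GeneModel("geneB", 2000), GeneModel("geneC", 500)]
    )


@pytest.fixture
def read_factory():
    """Build ReadAlignments from (read_id, [(gene, offset), ...]) pairs."""

    def build(spec):
        reads = []
        for read_id, locs in spec:
            reads.append(
                ReadAlignments(
                    read_id,
                    tuple(Alignment(read_id, g, off, "+") for g, off in locs),
                )
            )
        return reads

    return build
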