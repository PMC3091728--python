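import numpy as np
import pytest

from promoterscape import GeneAnnotation, SiteRecord, SyntheticConfig, simulate
from promoterscape.simulate import generate


@pytest.fixture
def toy_genes():
    """Hand-built genes: plus/minus strands, zero-length 5'UTR, divergent pair.

    g_plus : promoter [-300,-1] in the TSS frame (5'UTR length 0)
    g_minus: mirrored geometry, promoter [-150,-1], 5'UTR 20
    g_div_a/g_div_b: divergent pair sharing a 400-bp intergenic region
    g_no_tss: no mapped TSS (start-codon frame only)
    """
    return [
        GeneAnnotation("g_plus", "chrA", "+", cds_start=1001, upstream_boundary=700,
                       tss=1001),
        GeneAnnotation("g_minus", "chrA", "-", cds_start=5000, upstream_boundary=5171,
                       tss=5020),
        GeneAnnotation("g_div_a", "chrB", "-", cds_start=2000, upstream_boundary=2401,
                       tss=2060, bidirectional=True),
        GeneAnnotation("g_div_b", "chrB", "+", cds_start=2401, upstream_boundary=2000,
                       tss=2351, bidirectional=True),
        GeneAnnotation("g_no_tss", "chrA", "+", cds_start=9001, upstream_boundary=8800),
    ]


@pytest.fixture(scope="session")
def small_pkg():
    """In-memory synthetic package, small enough for per-test reuse."""
    return simulate(SyntheticConfig(n_genes=300, seed=7))


@pytest.fixture(scope="session")
def disk_pkg(tmp_path_factory):
    """Synthetic package written to disk once per session."""
    out = tmp_path_factory.mktemp("pkg")
    paths = generate(SyntheticConfig(n_genes=400, seed=11), out)
    return paths
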