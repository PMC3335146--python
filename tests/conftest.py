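import numpy as np
import pytest

from funnelcross.core import GeneticMap, rng_stream


def make_toy_map(n_markers=6, chrom="1", span_cM=40.0, is_x=False):
    """Evenly spaced markers over span_cM on a 1 Mb-per-marker grid."""
    return GeneticMap(
        chromosome_id=chrom,
        marker_ids=[f"{chrom}_m{k}" for k in range(n_markers)],
        positions_bp=np.arange(1, n_markers + 1) * 1_000_000,
        positions_cM=np.linspace(0.0, span_cM, n_markers),
        is_x=is_x,
    )


@pytest.fixture
def toy_map():
    return make_toy_map()


@pytest.fixture
def rng():
    return rng_stream(12345, "tests")
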