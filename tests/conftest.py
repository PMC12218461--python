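import numpy as np
import pytest

from polarity.io import CoverageTrack, GeneRecord
from polarity.tss import TSSRecord


@pytest.fixture
def simple_genes():
    """Two same-strand operonic genes plus an antisense gene."""
    return [
        GeneRecord("g0", "chr1", "+", 100, 300),
        GeneRecord("g1", "chr1", "+", 320, 600),
        GeneRecord("ga", "chr1", "-", 700, 900),
    ]


@pytest.fixture
def flat_tracks():
    """Normalized, featureless TEX+/- track pair."""
    def make(values):
        t = CoverageTrack("chr1", "+", np.asarray(values, float), 1, library_size=1000)
        t.normalized = True
        return t

    return make


def make_tss(pos, strand="+", height=50.0, tss_class="unassigned"):
    return TSSRecord("chr1", strand, pos, height, 10.0, 50.0, tss_class)


@pytest.fixture
def tss_factory():
    return make_tss
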