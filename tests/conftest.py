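import numpy as np
import pytest

from centrotime.genome import GenomeLayout
from centrotime.profiling import PipelineConfig
from centrotime.reads import new_read_set


@pytest.fixture
def layout():
    """Two 10 Mb chromosomes with mid-placed 1 Mb repeat-array centromeres."""
    from centrotime.simulate import build_toy_genome
    return build_toy_genome(n_chrom=2, chrom_length=10_000_000,
                            centromere_span=1_000_000, unit_length=171,
                            n_distinct_units=50, seed=1)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def plain_layout():
    """One plain 10 Mb chromosome, no annotation."""
    return GenomeLayout(chromosomes=[("chr1", 10_000_000)])


def make_reads(positions, chrom="chr1", strand="+", mapq=60, frag_len=400,
               paired=True):
    """Fragments with read-1 5' at the given positions (plus strand unless set)."""
    pos = np.asarray(positions, dtype=np.int64)
    strands = np.broadcast_to(np.asarray(strand, dtype=object), pos.shape).copy() \
        if not np.isscalar(strand) else np.full(len(pos), strand, dtype=object)
    start = np.where(strands == "+", pos, pos - frag_len)
    end = np.where(strands == "+", pos + frag_len, pos)
    mq = np.full(len(pos), mapq) if np.isscalar(mapq) else np.asarray(mapq)
    return new_read_set([chrom] * len(pos), start, end, strands, mq, paired=paired)


@pytest.fixture
def make_reads_factory():
    return make_reads
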