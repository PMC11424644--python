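import numpy as np
import pytest

from amp12q.genome import CNProfile, CNSegment, GenomeSpec, default_genome
from amp12q.simulate import toy_gene_models


@pytest.fixture
def genome():
    return default_genome()


@pytest.fixture
def male_genome():
    return default_genome(sex="male")


@pytest.fixture
def genes():
    return toy_gene_models()


@pytest.fixture
def toy_genome():
    """Single tiny chromosome for per-base oracles."""
    return GenomeSpec((("chr12", 10_000),))


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def profile_from_states(genome, chrom, states, sample="s"):
    """Build a single-chromosome profile with equal-width segments holding
    the given copy-number states (other chromosomes flat diploid)."""
    length = genome.length(chrom)
    width = length // len(states)
    segs = []
    for i, cn in enumerate(states):
        end = length if i == len(states) - 1 else (i + 1) * width
        segs.append(CNSegment(chrom, i * width, end, cn))
    for other, olen in genome.chromosomes:
        if other != chrom:
            from amp12q.genome import expected_ploidy
            segs.append(CNSegment(other, 0, olen,
                                  expected_ploidy(genome, other)))
    return CNProfile(sample, genome, segs)
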