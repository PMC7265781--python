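import numpy as np
import pytest

from scnpipe import binning as binning_mod


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length, gc=0.5):
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))


@pytest.fixture
def toy_genome(rng):
    """Two random chromosomes long enough that 25-mers are mostly unique."""
    return {
        "chr1": random_sequence(rng, 12000),
        "chr2": random_sequence(rng, 8000),
    }


@pytest.fixture
def toy_binning(toy_genome):
    mask = binning_mod.build_mappability(toy_genome, 25)
    gb = binning_mod.equipartition(mask, 40)
    return binning_mod.annotate_gc(toy_genome, gb)


def uniform_mask(n_positions, read_length=10, chrom="chr1"):
    """A mask where every position is mappable (synthetic, for partition tests)."""
    return binning_mod.MappabilityMask(
        read_length=read_length,
        masks={chrom: np.ones(n_positions, dtype=bool)},
        chrom_lengths={chrom: n_positions + read_length - 1},
    )
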