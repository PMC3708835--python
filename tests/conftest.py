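import numpy as np
import pytest

from apasensor.sequence_io import GeneModel, GenomeSequence, PolyASite

SEED = 0  # root seed for every seeded fixture/test in the suite


@pytest.fixture
def seed() -> int:
    return SEED


@pytest.fixture
def toy_genome() -> GenomeSequence:
    """One deterministic 600-nt chromosome, uniform random bases."""
    rng = np.random.default_rng(SEED)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def two_exon_plus_gene(toy_genome) -> GeneModel:
    """Plus-strand gene: exons [50,100) and [200,260), intron [100,200)."""
    pa = PolyASite("chr1", "+", 250, gene_id="gplus", label="proximal")
    return GeneModel(
        gene_id="gplus", chrom="chr1", strand="+", exons=[(50, 100), (200, 260)], pa_sites=[pa]
    )
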