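import numpy as np
import pytest

from dnacanvas.fixtures import gen_genome
from dnacanvas.io_formats import Contig, write_fasta
from dnacanvas.tile_layout import TileLayout


@pytest.fixture(scope="session")
def small_genome():
    """Three seeded contigs totalling 3000 bp."""
    return gen_genome(n_contigs=3, lengths=[1500, 1000, 500], seed=11)


@pytest.fixture
def small_genome_fasta(tmp_path, small_genome):
    path = tmp_path / "genome.fa"
    write_fasta(small_genome, path)
    return path


@pytest.fixture(scope="session")
def default_layout():
    return TileLayout()


@pytest.fixture
def toy_layout():
    """A tiny tile layout whose full index space can be enumerated."""
    return TileLayout(radices=(10, 10, 4, 3), paddings=(0, 0, 2, 1))


def random_contig(length, seed, name="chr1"):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", "S1")
    return Contig(name, bases[rng.integers(0, 4, length)].tobytes().decode())
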