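import warnings

import numpy as np
import pytest

from lcrtools import BlockSpec, make_planted_proteome
from lcrtools.calling import LcrCall
from lcrtools.io import SequenceInterval

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="umap|scanpy|anndata")


def write_fasta(path, entries, width=60):
    """entries: list of (header, sequence). Returns path."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


@pytest.fixture
def fasta_factory(tmp_path):
    def make(entries, name="test.fasta"):
        return write_fasta(tmp_path / name, entries)

    return make


@pytest.fixture(scope="session")
def paired_block_proteome():
    """40 proteins, each with two planted 18-mer poly-K blocks (a same-type pair)."""
    return make_planted_proteome(
        40,
        (220, 320),
        [BlockSpec(18, "K"), BlockSpec(18, "K")],
        seed=11,
        name="paired",
    )


def island_calls(n_per_island=300, length=20, residues=("K", "E")):
    """Synthetic LCR calls forming pure composition islands (one per residue)."""
    calls = []
    for res in residues:
        for i in range(n_per_island):
            iv = SequenceInterval(f"p{res}{i}", 1, length)
            calls.append(LcrCall(iv, res * length, lcr_index=1))
    return calls


@pytest.fixture(scope="session")
def two_island_comp():
    from lcrtools import composition_matrix

    return composition_matrix(island_calls())
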