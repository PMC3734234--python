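import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bacevol import synthetic


@pytest.fixture(scope="session")
def small_bundle():
    """One modest simulated species shared by read-only tests."""
    return synthetic.simulate_species(
        n_genes=120, n_codons_mean=150, beta_map={"CAI": -0.8}, seed=7)


@pytest.fixture()
def fasta_file(tmp_path):
    """Write a small in-frame CDS FASTA and return its path."""
    path = tmp_path / "genes.fasta"
    path.write_text(
        ">geneA 0 9 +\nATGAAAGTG\n"
        ">geneB 100 112 -\nATGCCGCTGTGA\n"
    )
    return path
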