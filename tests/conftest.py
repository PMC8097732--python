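import pytest

from trnaends.simulate import generate_reference


@pytest.fixture(scope="session")
def window():
    """Synthetic reference window (71-nt gene, 60-nt flanks) shared by tests."""
    return generate_reference(seed=11)


@pytest.fixture()
def tiny_genome(tmp_path):
    """A 500-nt genome with the gene at 1-based 100..170 and known flanks."""
    import numpy as np

    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    fasta = tmp_path / "genome.fasta"
    fasta.write_text(f">chr1\n{seq}\n")
    bed = tmp_path / "locus.bed"
    bed.write_text("chr1\t99\t170\ttrnD-Cys\t.\t+\n")
    return {"fasta": fasta, "bed": bed, "seq": seq}
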