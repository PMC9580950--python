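import pytest

from srnakit.fixtures import make_fixture_records
from srnakit.reference_io import write_reference


@pytest.fixture(scope="session")
def toy_records():
    """Small mixed reference set: 10 miRNA, 5 piRNA, 3 novel on 2 chromosomes."""
    return make_fixture_records(
        n_mirna=10, n_pirna=5, n_novel=3, n_chromosomes=2, rng_seed=7
    )


@pytest.fixture
def toy_reference_files(tmp_path, toy_records):
    fasta = tmp_path / "ref.fa"
    gff = tmp_path / "ref.gff3"
    write_reference(toy_records, fasta, gff)
    return fasta, gff
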