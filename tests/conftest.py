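import pytest

from asmsv.model import Parameters
from asmsv.synthetic_genome import make_benchmark_fixture, write_fasta, write_sam

FIXTURE_SEED = 20214


@pytest.fixture()
def params():
    return Parameters()


@pytest.fixture(scope="session")
def benchmark_fixture():
    """Standard diploid fixture: 2 x 250 kb, all six SV classes, mixed zygosity."""
    return make_benchmark_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def benchmark_sams(benchmark_fixture, tmp_path_factory):
    directory = tmp_path_factory.mktemp("benchmark_sams")
    paths = {}
    for hap in (1, 2):
        path = directory / f"hap{hap}.sam"
        write_sam(path, benchmark_fixture["header"], benchmark_fixture["records"][hap])
        paths[hap] = str(path)
    return paths


@pytest.fixture(scope="session")
def benchmark_reference_fasta(benchmark_fixture, tmp_path_factory):
    path = tmp_path_factory.mktemp("benchmark_ref") / "reference.fa"
    write_fasta(path, benchmark_fixture["reference"])
    return str(path)
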