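import pytest

from wellseq import simdata


@pytest.fixture(scope="session")
def scheme():
    return simdata.default_scheme("plate1")


@pytest.fixture(scope="session")
def amplicons():
    """Five well-separated synthetic V4 amplicons with toy lineages."""
    return simdata.simulate_amplicons(5, seed=3)


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    """A ~30-sequence toy taxonomy reference FASTA."""
    amps = simdata.simulate_amplicons(30, seed=11)
    path = tmp_path_factory.mktemp("ref") / "toy_reference.fasta"
    simdata.write_reference_fasta(amps, path)
    return path, amps
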