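import pytest

from loteva.synthetic import SortingParams, build_transcriptome, simulate_steady_states


@pytest.fixture(scope="session")
def small_txome():
    """A 60-gene synthetic transcriptome shared across read-level tests."""
    return build_transcriptome(60, SortingParams(), seed=7)


@pytest.fixture(scope="session")
def small_truth(small_txome):
    return simulate_steady_states(small_txome, SortingParams(), seed=8)


@pytest.fixture(scope="session")
def annotation_files(tmp_path_factory, small_txome):
    """The small transcriptome written to GTF/FASTA/BED on disk."""
    d = tmp_path_factory.mktemp("annotation")
    small_txome.write(d)
    return d
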