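import pytest

from rosfam.sim import simulate_dataset


@pytest.fixture(scope="session")
def study_bundle():
    """One full study-condition dataset shared by read-only tests."""
    return simulate_dataset(seed=3)


@pytest.fixture(scope="session")
def emitted_dataset(study_bundle, tmp_path_factory):
    """The same dataset written to disk (GFF3/FASTA/TSV)."""
    from rosfam.sim.emit import emit_dataset

    out = tmp_path_factory.mktemp("dataset")
    emit_dataset(
        study_bundle.annotations,
        out,
        counts=study_bundle.counts,
        results=study_bundle.results,
        seed=99,
    )
    return out
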