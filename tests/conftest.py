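import pytest

from mocrkit import seqio


@pytest.fixture
def toy_alignment():
    rows = [
        seqio.SequenceRecord(id="a", residues="ACDE"),
        seqio.SequenceRecord(id="b", residues="ACDF"),
        seqio.SequenceRecord(id="c", residues="AC-E"),
    ]
    return seqio.Alignment(rows=rows, alphabet="protein")


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The bundled synthetic input set, generated once per session."""
    from mocrkit.pipeline import generate_fixture

    outdir = tmp_path_factory.mktemp("bundle")
    return generate_fixture(outdir, seed=0)
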