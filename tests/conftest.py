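import pytest

from famgram import build_vocabulary


@pytest.fixture(scope="session")
def vocab():
    """Default full vocabulary: types 1-4, 340 dimensions."""
    return build_vocabulary({1, 2, 3, 4})


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
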