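import numpy as np
import pytest

from lipscreen.seqio import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing FASTA content to a temp file and returning its path."""

    def _write(content: str, name: str = "input.fasta"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


@pytest.fixture
def tsv_file(tmp_path):
    def _write(content: str, name: str = "table.tsv"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def make_record(sequence: str, rec_id: str = "p1") -> ProteinRecord:
    return ProteinRecord(id=rec_id, sequence=sequence)
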