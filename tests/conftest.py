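import numpy as np
import pytest

from bzipkit.records import AMINO_ACIDS, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20180926)


@pytest.fixture
def random_protein(rng):
    def make(length: int, rec_id: str = "r") -> ProteinRecord:
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        return ProteinRecord(id=rec_id, sequence=seq)

    return make


@pytest.fixture
def write_fasta_file(tmp_path):
    def write(text: str, name: str = "in.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
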