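import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from pasmap import PASVariantTable, SequenceLogo, TranscriptRecord


@pytest.fixture(scope="session")
def default_table() -> PASVariantTable:
    return PASVariantTable.default()


@pytest.fixture(scope="session")
def default_logo() -> SequenceLogo:
    return SequenceLogo.default()


@pytest.fixture
def make_record():
    def _make(seq: str, tx_id: str = "tx1", gene_id: str = None, gene_class="mRNA"):
        return TranscriptRecord(
            transcript_id=tx_id,
            gene_id=gene_id or tx_id,
            gene_class=gene_class,
            sequence=seq,
        )

    return _make


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(entries: dict[str, str], name: str = "input.fasta") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries.items():
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
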