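import textwrap

import pytest

from barcodegap.sequence_io import Alignment, BarcodeRecord


@pytest.fixture
def toy_alignment():
    """Three 12-column records with full taxonomy labels."""
    return Alignment(records=(
        BarcodeRecord(id="s1", sequence="ACGTACGTACGT",
                      species="X", genus="G", family="F"),
        BarcodeRecord(id="s2", sequence="ACGTACGTACGA",
                      species="X", genus="G", family="F"),
        BarcodeRecord(id="s3", sequence="ACGTACGAACGA",
                      species="Y", genus="G", family="F"),
    ))


@pytest.fixture
def fasta_factory(tmp_path):
    """Write a FASTA (and optional taxonomy TSV) from dicts; returns paths."""

    def _write(seqs: dict[str, str], taxonomy: dict[str, tuple] | None = None):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        tax_path = None
        if taxonomy is not None:
            tax_path = tmp_path / "tax.tsv"
            lines = ["id\tspecies\tgenus\tfamily\tgroup"]
            for rec_id, labels in taxonomy.items():
                lines.append("\t".join([rec_id, *labels]))
            tax_path.write_text("\n".join(lines) + "\n")
        return fasta, tax_path

    return _write
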