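"""Shared fixtures: tiny hand-built proteins and on-disk tables."""

from __future__ import annotations

import pytest

from mechnet.annotations_io import ProteinRecord


def make_protein(acc: str, seq: str, gene: str | None = None,
                 taxon: str = "human") -> ProteinRecord:
    rec = ProteinRecord(accession=acc, gene=gene or acc, taxon=taxon,
                        sequence=seq)
    rec.validate()
    return rec


@pytest.fixture
def two_proteins(tmp_path):
    """A two-sequence FASTA plus matching metadata table on disk."""
    fasta = tmp_path / "seqs.fa"
    fasta.write_text(">P00001\nMKTAYIAKQR\n>P00002\nGGSAAATGGWW\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "accession\tgene\ttaxon\n"
        "P00001\tGENE1\thuman\n"
        "P00002\tGENE2\thuman\n")
    return fasta, meta


def write_tsv(path, header: str, rows: list[str]) -> None:
    path.write_text("\n".join([header, *rows]) + "\n")
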