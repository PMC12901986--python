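"""FASTA reading/writing for transcript sequences (RNA alphabet kept as-is)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..simkit.transcriptome import Transcriptome

__all__ = ["write_fasta", "read_fasta"]


def write_fasta(tx: Transcriptome, path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=t.id,
            description=f"biotype={t.biotype} abundance={t.abundance:.6g}",
        )
        for t in tx.transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by id; T is normalized to U."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }
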