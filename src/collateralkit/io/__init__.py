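"""Format readers and writers shared by the CLI and pipeline."""

from .bed import write_sites_bed, write_truth_bed
from .fasta import read_fasta, write_fasta
from .paf import parse_paf, write_paf
from .sam import parse_sam
from .tables import (
    read_counts_tsv,
    read_cq_csv,
    read_electropherogram_tsv,
    read_sample_sheet,
    read_sites_tsv,
    write_counts_tsv,
    write_cq_csv,
    write_electropherogram_tsv,
    write_fold_change_tsv,
    write_pfm_tsv,
    write_sample_sheet,
    write_sites_tsv,
)

__all__ = [
    "parse_alignments",
    "parse_paf",
    "parse_sam",
    "read_counts_tsv",
    "read_cq_csv",
    "read_electropherogram_tsv",
    "read_fasta",
    "read_sample_sheet",
    "read_sites_tsv",
    "write_counts_tsv",
    "write_cq_csv",
    "write_electropherogram_tsv",
    "write_fasta",
    "write_fold_change_tsv",
    "write_paf",
    "write_pfm_tsv",
    "write_sample_sheet",
    "write_sites_bed",
    "write_sites_tsv",
    "write_truth_bed",
]


def parse_alignments(path, format: str = "paf", fasta: "dict[str, str] | None" = None):
    """Parse alignments from PAF or SAM/BAM, keeping primary records.

    When ``fasta`` sequences are supplied, reference lengths are
    cross-checked against them.
    """
    from ..errors import FormatError

    if format == "paf":
        aln = parse_paf(path)
    elif format in ("sam", "bam"):
        aln = parse_sam(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if fasta is not None:
        for tid, length in aln.transcript_lengths.items():
            if tid in fasta and len(fasta[tid]) != length:
                raise FormatError(
                    f"transcript {tid!r}: alignment length {length} != "
                    f"FASTA length {len(fasta[tid])}"
                )
    return aln
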