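"""SAM/BAM reading (read-only; PAF is the canonical format).

Secondary (0x100) and supplementary (0x800) records are dropped with a
logged count; coordinates come out 0-based half-open from pysam.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pysam

from ..alignments import AlignmentRecord, AlignmentSet
from ..errors import FormatError

__all__ = ["parse_sam"]

logger = logging.getLogger(__name__)


def parse_sam(path: str | Path) -> AlignmentSet:
    records: list[AlignmentRecord] = []
    n_dropped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.is_secondary or aln.is_supplementary:
                n_dropped += 1
                continue
            if aln.reference_name not in lengths:
                raise FormatError(
                    f"record {aln.query_name!r} maps to unknown reference "
                    f"{aln.reference_name!r}"
                )
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    transcript_id=aln.reference_name,
                    tstart=int(aln.reference_start),
                    tend=int(aln.reference_end),
                    is_primary=True,
                    mapq=int(aln.mapping_quality),
                    strand="-" if aln.is_reverse else "+",
                )
            )
    if n_dropped:
        logger.info("dropped %d secondary/supplementary SAM records", n_dropped)
    if not records:
        warnings.warn(f"no alignment records parsed from {path}")
    return AlignmentSet(records, lengths)
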