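"""PAF is the canonical alignment interchange format of the toolkit.

Twelve mandatory tab-separated columns; the toolkit writes primary
records only and marks them with the ``tp:A:P`` tag. Reads are emitted as
end-to-end query alignments (qstart 0, qend = qlen = mapped length) on
the forward strand of the transcript.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

from ..alignments import AlignmentRecord, AlignmentSet
from ..errors import FormatError, ValidationError

__all__ = ["write_paf", "parse_paf"]

logger = logging.getLogger(__name__)


def write_paf(alignments: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in alignments.primary_records():
            tlen = alignments.transcript_lengths[rec.transcript_id]
            span = rec.tend - rec.tstart
            fields = [
                rec.read_id,
                str(span),  # qlen
                "0",  # qstart
                str(span),  # qend
                rec.strand,
                rec.transcript_id,
                str(tlen),
                str(rec.tstart),
                str(rec.tend),
                str(span),  # matches
                str(span),  # alignment block length
                str(rec.mapq),
                "tp:A:P",
            ]
            fh.write("\t".join(fields) + "\n")


def parse_paf(path: str | Path) -> AlignmentSet:
    """Parse a PAF file, keeping primary records only.

    Records tagged ``tp:A:S`` (secondary) or ``tp:A:I`` (inversion) are
    dropped with a logged count; coordinates are already 0-based
    half-open in PAF.
    """
    records: list[AlignmentRecord] = []
    lengths: dict[str, int] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"PAF record has {len(fields)} columns, expected >= 12",
                    line=lineno,
                )
            try:
                qname = fields[0]
                strand = fields[4]
                tname = fields[5]
                tlen = int(fields[6])
                tstart = int(fields[7])
                tend = int(fields[8])
                mapq = int(fields[11])
            except ValueError as exc:
                raise FormatError(f"unparsable PAF field: {exc}", line=lineno)
            tags = fields[12:]
            tp = next((t.split(":")[-1] for t in tags if t.startswith("tp:A:")), "P")
            if tp != "P":
                n_dropped += 1
                continue
            if tname in lengths and lengths[tname] != tlen:
                raise FormatError(
                    f"inconsistent length for target {tname!r}: "
                    f"{lengths[tname]} vs {tlen}",
                    line=lineno,
                )
            lengths[tname] = tlen
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    transcript_id=tname,
                    tstart=tstart,
                    tend=tend,
                    is_primary=True,
                    mapq=mapq,
                    strand=strand,
                )
            )
    if n_dropped:
        logger.info("dropped %d non-primary PAF records", n_dropped)
    if not records:
        warnings.warn(f"no alignment records parsed from {path}")
    try:
        return AlignmentSet(records, lengths)
    except ValidationError as exc:
        raise FormatError(str(exc))
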