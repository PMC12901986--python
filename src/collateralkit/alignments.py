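"""Transcript-space read alignments.

Coordinates are 0-based half-open on the forward strand of the transcript.
Secondary/supplementary records are dropped at parse time, so an
:class:`AlignmentSet` normally contains primary records only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import ValidationError

__all__ = ["AlignmentRecord", "AlignmentSet"]


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    transcript_id: str
    tstart: int
    tend: int
    is_primary: bool = True
    mapq: int = 60
    strand: str = "+"

    @property
    def mapped_length(self) -> int:
        return self.tend - self.tstart


@dataclass
class AlignmentSet:
    """A bag of alignment records plus the reference transcript lengths."""

    records: list[AlignmentRecord] = field(default_factory=list)
    transcript_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rec in self.records:
            length = self.transcript_lengths.get(rec.transcript_id)
            if length is None:
                raise ValidationError(
                    f"record {rec.read_id!r} refers to unknown transcript "
                    f"{rec.transcript_id!r}"
                )
            if not (0 <= rec.tstart < rec.tend <= length):
                raise ValidationError(
                    f"record {rec.read_id!r} interval [{rec.tstart}, {rec.tend}) "
                    f"outside transcript {rec.transcript_id!r} of length {length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AlignmentRecord]:
        return iter(self.records)

    def primary_records(self) -> Iterable[AlignmentRecord]:
        return (r for r in self.records if r.is_primary)

    def records_for(self, transcript_id: str) -> list[AlignmentRecord]:
        return [r for r in self.records if r.transcript_id == transcript_id]
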