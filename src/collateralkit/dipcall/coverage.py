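"""Per-transcript depth profiles from transcript-space alignments."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..alignments import AlignmentSet
from ..errors import ValidationError

__all__ = ["CoverageProfile", "transcript_coverage"]


@dataclass
class CoverageProfile:
    transcript_id: str
    depth: np.ndarray
    n_reads: int
    covered: bool = True  # False when n_reads < min_reads

    @property
    def length(self) -> int:
        return int(self.depth.size)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0

    @property
    def relative_depth(self) -> np.ndarray:
        """Depth divided by the transcript mean depth (mean 1 when covered)."""
        mean = self.mean_depth
        if mean == 0:
            return np.zeros_like(self.depth, dtype=float)
        return self.depth / mean


def transcript_coverage(
    alignments: AlignmentSet, transcript_id: str, min_reads: int = 1
) -> CoverageProfile:
    """Depth per position from primary records of one transcript.

    ``depth[i]`` counts primary records with ``tstart <= i < tend``.
    """
    length = alignments.transcript_lengths.get(transcript_id)
    if length is None:
        raise ValidationError(f"unknown transcript {transcript_id!r}")
    delta = np.zeros(length + 1, dtype=np.int64)
    n_reads = 0
    for rec in alignments.primary_records():
        if rec.transcript_id != transcript_id:
            continue
        delta[rec.tstart] += 1
        delta[rec.tend] -= 1
        n_reads += 1
    depth = np.cumsum(delta[:-1])
    return CoverageProfile(
        transcript_id=transcript_id,
        depth=depth,
        n_reads=n_reads,
        covered=n_reads >= min_reads,
    )
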