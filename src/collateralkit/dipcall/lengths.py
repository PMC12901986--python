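"""Read-length QC: mapped length versus reference transcript length.

The full-length read fraction (ratio >= 0.9 by default) collapses the
mapped-vs-reference density into one degradation-sensitive statistic.
Hyper-abundant artifact transcripts (e.g. histones, or genes hit by a
co-mapping snRNA) can be excluded by id before summarizing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..alignments import AlignmentSet
from ..errors import ValidationError

__all__ = ["mapped_length_stats"]


def mapped_length_stats(
    alignments: AlignmentSet,
    exclusions: tuple[str, ...] = (),
    full_length_ratio: float = 0.9,
    transcript_ids: "set[str] | None" = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-read mapped/reference lengths and their summary.

    Returns ``(per_read, summary)`` where ``per_read`` has columns
    ``read_id, transcript_id, mapped_length, reference_length, ratio``
    and ``summary`` reports the median ratio and the fraction of reads
    with ratio >= ``full_length_ratio``.
    """
    excluded = set(exclusions)
    rows = []
    for rec in alignments.primary_records():
        if rec.transcript_id in excluded:
            continue
        if transcript_ids is not None and rec.transcript_id not in transcript_ids:
            continue
        ref_len = alignments.transcript_lengths.get(rec.transcript_id)
        if ref_len is None:
            raise ValidationError(
                f"no reference length for transcript {rec.transcript_id!r}"
            )
        rows.append(
            {
                "read_id": rec.read_id,
                "transcript_id": rec.transcript_id,
                "mapped_length": rec.mapped_length,
                "reference_length": ref_len,
                "ratio": rec.mapped_length / ref_len,
            }
        )
    per_read = pd.DataFrame(
        rows,
        columns=["read_id", "transcript_id", "mapped_length", "reference_length", "ratio"],
    )
    if per_read.empty:
        summary = {"n_reads": 0, "median_ratio": np.nan, "full_length_fraction": np.nan}
    else:
        summary = {
            "n_reads": int(len(per_read)),
            "median_ratio": float(per_read["ratio"].median()),
            "full_length_fraction": float(
                (per_read["ratio"] >= full_length_ratio).mean()
            ),
        }
    return per_read, summary
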