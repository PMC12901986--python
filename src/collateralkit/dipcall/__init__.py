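"""Coverage-dip cleavage-site calling from transcript-space long reads."""

import logging

from ..errors import LowCoverageError
from .context import ContextSummary, assign_cleavage_sites, cleavage_context_pfm
from .coverage import CoverageProfile, transcript_coverage
from .dips import DEFAULT_DIP_PARAMS, DipCall, detect_dips
from .lengths import mapped_length_stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DIP_PARAMS",
    "ContextSummary",
    "CoverageProfile",
    "DipCall",
    "assign_cleavage_sites",
    "call_transcriptome_dips",
    "cleavage_context_pfm",
    "detect_dips",
    "mapped_length_stats",
    "transcript_coverage",
]


def call_transcriptome_dips(
    alignments,
    sequences: dict[str, str],
    upstream_search: int = 5,
    context_flank: int = 5,
    **dip_params,
) -> list[DipCall]:
    """Detect dips and assign cleavage uracils across all transcripts.

    Transcripts below the minimum mean depth are skipped with a log
    entry; all other dip-caller knobs pass through to
    :func:`detect_dips`.
    """
    calls: list[DipCall] = []
    for transcript_id in sorted(alignments.transcript_lengths):
        profile = transcript_coverage(alignments, transcript_id)
        try:
            dips = detect_dips(profile, **dip_params)
        except LowCoverageError as exc:
            logger.info("skipping %s: %s", transcript_id, exc)
            continue
        seq = sequences.get(transcript_id)
        if seq is None:
            logger.warning("no sequence for %s; dips left unassigned", transcript_id)
            calls.extend(dips)
            continue
        calls.extend(
            assign_cleavage_sites(
                dips, seq, upstream_search=upstream_search, context_flank=context_flank
            )
        )
    return calls
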