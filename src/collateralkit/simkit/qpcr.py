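"""qPCR quantification-cycle simulation for the 5'-3' integrity assay.

Reverse transcription is oligo-dT primed, so a molecule templates an
amplicon only if it has no cut anywhere between that amplicon's 5'
boundary and the transcript 3' end. A 5'-located amplicon therefore loses
template faster than a 3' one as degradation proceeds, and

``Cq = cq_intercept - log(template) / log(1 + E) + N(0, noise_sd)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._rng import rng_from_seed
from ..errors import ValidationError
from .cleavage import FragmentPool

__all__ = [
    "QpcrAssay",
    "amplicon_templates",
    "templates_from_cut_fraction",
    "simulate_cq_table",
]

PRIMER_ENDS = ("5p", "3p")


@dataclass(frozen=True)
class QpcrAssay:
    """Primer-pair layout on a target transcript (0-based half-open)."""

    target_id: str
    amplicon_5p: tuple[int, int]
    amplicon_3p: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (s, e) in (
            ("amplicon_5p", self.amplicon_5p),
            ("amplicon_3p", self.amplicon_3p),
        ):
            if not (0 <= s < e):
                raise ValidationError(f"{name} interval [{s}, {e}) invalid")
        if self.amplicon_3p[0] < self.amplicon_5p[1]:
            raise ValidationError("amplicon_3p must lie 3' of amplicon_5p")


def amplicon_templates(pool: FragmentPool, assay: QpcrAssay) -> dict[str, float]:
    """Effective template molecules per primer end.

    A molecule counts for an amplicon iff its poly-A-anchored (3'-terminal)
    fragment starts at or before the amplicon's 5' boundary, i.e. no cut
    lies strictly between that boundary and the transcript 3' end.
    """
    length = pool.transcript_lengths.get(assay.target_id)
    if length is None:
        raise ValidationError(f"pool lacks transcript {assay.target_id!r}")
    if assay.amplicon_3p[1] > length:
        raise ValidationError("amplicon_3p extends past the transcript 3' end")
    templates = {end: 0.0 for end in PRIMER_ENDS}
    boundaries = {"5p": assay.amplicon_5p[0], "3p": assay.amplicon_3p[0]}
    for frag in pool.fragments:
        if frag.transcript_id != assay.target_id or frag.end != length:
            continue
        for end, boundary in boundaries.items():
            if frag.start <= boundary:
                templates[end] += 1
    return templates


def templates_from_cut_fraction(
    n_molecules: float, cut_fraction: float
) -> dict[str, float]:
    """Templates when a fraction of molecules is cut between the amplicons
    (and nowhere else)."""
    if not (0.0 <= cut_fraction <= 1.0):
        raise ValidationError("cut_fraction must be in [0, 1]")
    return {"5p": n_molecules * (1.0 - cut_fraction), "3p": float(n_molecules)}


def simulate_cq_table(
    templates: dict[str, float] | FragmentPool,
    sample: str,
    target: str,
    efficiency: float = 1.0,
    cq_intercept: float = 38.0,
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
    assay: QpcrAssay | None = None,
) -> pd.DataFrame:
    """Simulate replicate Cq measurements for both primer ends.

    ``templates`` is either a mapping ``{"5p": t5, "3p": t3}`` or a
    :class:`FragmentPool` (then ``assay`` is required). Zero effective
    template yields ``detected = False`` rows with NaN Cq.
    """
    if not (0.0 < efficiency <= 1.0):
        raise ValidationError("efficiency must be in (0, 1]")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if isinstance(templates, FragmentPool):
        if assay is None:
            raise ValidationError("assay required when templates is a FragmentPool")
        templates = amplicon_templates(templates, assay)
    unknown = set(templates) - set(PRIMER_ENDS)
    if unknown:
        raise ValidationError(f"unknown primer ends: {sorted(unknown)}")

    rng = rng_from_seed(seed)
    rows = []
    log_base = math.log(1.0 + efficiency)
    for end in PRIMER_ENDS:
        template = templates.get(end, 0.0)
        for rep in range(1, n_replicates + 1):
            if template <= 0:
                rows.append(
                    {
                        "sample": sample,
                        "target": target,
                        "primer_end": end,
                        "replicate": rep,
                        "cq": np.nan,
                        "detected": False,
                    }
                )
                continue
            cq = cq_intercept - math.log(template) / log_base
            if noise_sd > 0:
                cq += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "primer_end": end,
                    "replicate": rep,
                    "cq": cq,
                    "detected": True,
                }
            )
    return pd.DataFrame(rows)
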