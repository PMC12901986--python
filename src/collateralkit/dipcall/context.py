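"""Cleavage-position assignment and sequence-context summaries.

The cleavage position of a dip is taken to be the uracil closest to the
dip's 5' boundary, searching both a short window upstream of the dip and
the dip interior (ties favor the upstream candidate). Assigned sites are
summarized as a position frequency matrix over a window centred on the U,
with per-position information content and a dinucleotide table at
positions (0, +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ValidationError
from .dips import DipCall

__all__ = ["ContextSummary", "assign_cleavage_sites", "cleavage_context_pfm"]

ALPHABET = ("A", "C", "G", "U")


def assign_cleavage_sites(
    dips: list[DipCall],
    sequence: str,
    upstream_search: int = 5,
    context_flank: int = 5,
) -> list[DipCall]:
    """Assign the cleavage uracil for each dip on one transcript.

    Candidates are U positions inside the dip or within ``upstream_search``
    nt 5' of the dip start; the candidate minimizing absolute distance to
    the dip's 5' boundary wins, ties going to the upstream one. A dip with
    no U in the window is retained with ``position=None``.
    """
    out = []
    n = len(sequence)
    for dip in dips:
        if dip.end > n:
            raise ValidationError(
                f"dip [{dip.start}, {dip.end}) outside sequence of length {n}"
            )
        lo = max(0, dip.start - upstream_search)
        candidates = [p for p in range(lo, dip.end) if sequence[p] == "U"]
        if not candidates:
            out.append(dip.with_position(None))
            continue
        # min distance; ties resolved upstream because candidates are
        # scanned in coordinate order and strict inequality keeps the
        # earlier (more 5') one
        best = min(candidates, key=lambda p: abs(p - dip.start))
        context = sequence[max(0, best - context_flank) : best + context_flank + 1]
        dinuc = sequence[best : best + 2] if best + 2 <= n else None
        out.append(dip.with_position(best, context=context, dinucleotide=dinuc))
    return out


@dataclass
class ContextSummary:
    """Aligned-window composition around assigned cleavage sites."""

    pfm: pd.DataFrame  # rows: positions -flank..+flank; columns: A,C,G,U
    information_content: pd.Series  # bits per position
    dinucleotide_counts: pd.Series  # counts of (0, +1) dinucleotides
    n_sites: int

    def us_fraction(self) -> float:
        """Fraction of sites with U followed by a strong (G/C) base."""
        total = int(self.dinucleotide_counts.sum())
        if total == 0:
            return float("nan")
        us = sum(
            int(c)
            for d, c in self.dinucleotide_counts.items()
            if len(d) == 2 and d[1] in "GC"
        )
        return us / total


def cleavage_context_pfm(
    calls: list[DipCall],
    sequences: dict[str, str],
    flank: int = 5,
    small_sample_correction: bool = False,
) -> ContextSummary:
    """Position frequency matrix around assigned cleavage sites.

    Windows extending past either transcript end are excluded. Information
    content per position is ``2 - H`` bits (Shannon entropy over ACGU),
    optionally with the small-sample correction ``3 / (2 ln 2 n)``.
    """
    windows = []
    dinucs = []
    for call in calls:
        if call.position is None:
            continue
        seq = sequences.get(call.transcript_id)
        if seq is None:
            raise ValidationError(
                f"no sequence for transcript {call.transcript_id!r}"
            )
        p = call.position
        if seq[p] != "U":
            raise ValidationError(
                f"assigned position {p} on {call.transcript_id!r} is not a U"
            )
        if p - flank < 0 or p + flank + 1 > len(seq):
            continue  # truncated window
        windows.append(seq[p - flank : p + flank + 1])
        if p + 2 <= len(seq):
            dinucs.append(seq[p : p + 2])
    if not windows:
        raise ValidationError("no assigned sites with complete context windows")

    n = len(windows)
    positions = list(range(-flank, flank + 1))
    counts = np.zeros((len(positions), len(ALPHABET)), dtype=float)
    lookup = {b: j for j, b in enumerate(ALPHABET)}
    for w in windows:
        for i, base in enumerate(w):
            counts[i, lookup[base]] += 1
    pfm = pd.DataFrame(counts / n, index=positions, columns=list(ALPHABET))
    pfm.index.name = "position"

    probs = pfm.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = 2.0 - entropy
    if small_sample_correction:
        ic = ic - 3.0 / (2.0 * np.log(2.0) * n)
    information = pd.Series(np.clip(ic, 0.0, 2.0), index=pfm.index, name="bits")

    dinuc_counts = pd.Series(dinucs, dtype="object").value_counts().sort_index()
    dinuc_counts.name = "count"
    return ContextSummary(
        pfm=pfm,
        information_content=information,
        dinucleotide_counts=dinuc_counts,
        n_sites=n,
    )
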