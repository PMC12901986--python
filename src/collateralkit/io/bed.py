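"""BED6 writers for dips and planted ground-truth sites.

0-based half-open per BED convention, forward strand, deterministic
ordering by (chrom, start).
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["write_sites_bed", "write_truth_bed"]


def write_sites_bed(calls, path: str | Path) -> None:
    """Dip calls as BED6: chrom = transcript, interval = dip,
    score = round(1000 * (1 - depth ratio))."""
    rows = sorted(calls, key=lambda c: (c.transcript_id, c.start))
    with open(path, "w") as fh:
        for c in rows:
            score = int(round(1000 * (1.0 - c.depth_ratio)))
            score = max(0, min(1000, score))
            name = c.transcript_id
            fh.write(
                f"{c.transcript_id}\t{c.start}\t{c.end}\t{name}\t{score}\t+\n"
            )


def write_truth_bed(sites, path: str | Path) -> None:
    """Planted site annotation (transcript_id -> [(position, weight)]) as
    BED6 single-base intervals; score encodes the hazard weight."""
    rows = []
    for transcript_id, site_list in sites.items():
        for position, weight in site_list:
            rows.append((transcript_id, position, weight))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for transcript_id, position, weight in rows:
            score = max(0, min(1000, int(round(weight * 100))))
            fh.write(
                f"{transcript_id}\t{position}\t{position + 1}\tsite\t{score}\t+\n"
            )
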