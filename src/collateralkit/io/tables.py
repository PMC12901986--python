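"""Tabular readers/writers: counts TSV, Cq CSV, electropherogram TSV,
sample sheets, and cleavage-site tables.

All TSVs are tab-separated with a header line, UTF-8, '#' comments
permitted. Write-then-read reproduces the in-memory structure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..assays import Electropherogram
from ..errors import FormatError
from ..spikenorm import CountMatrix

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_cq_csv",
    "read_cq_csv",
    "write_electropherogram_tsv",
    "read_electropherogram_tsv",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_sites_tsv",
]


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    """Counts TSV: gene_id, spike_in, optional biotype, then sample columns."""
    out = pd.DataFrame(index=cm.counts.index)
    out.index.name = "gene_id"
    out["spike_in"] = cm.spike_in.astype(bool)
    if cm.biotypes is not None:
        out["biotype"] = cm.biotypes
    for col in cm.counts.columns:
        out[col] = cm.counts[col]
    out.to_csv(path, sep="\t")


def read_counts_tsv(
    path: str | Path, sample_sheet: pd.DataFrame | None = None
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
    if "spike_in" not in df.columns:
        raise FormatError(f"counts table {path} lacks a spike_in column")
    spike = df.pop("spike_in").astype(bool)
    biotypes = df.pop("biotype") if "biotype" in df.columns else None
    counts = df.apply(pd.to_numeric)
    if sample_sheet is not None:
        samples = sample_sheet.set_index("sample")
    else:
        samples = pd.DataFrame(
            {"condition": pd.Series("unknown", index=counts.columns)}
        )
    return CountMatrix(counts=counts, spike_in=spike, samples=samples, biotypes=biotypes)


def write_cq_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Cq CSV columns: sample, target, primer_end, replicate, cq, detected.

    Undetected wells keep an empty cq field (the "not detected" sentinel).
    """
    out = table[["sample", "target", "primer_end", "replicate", "cq", "detected"]]
    out.to_csv(path, index=False)


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"sample", "target", "primer_end", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"Cq table {path} missing columns: {sorted(missing)}")
    if "detected" not in df.columns:
        df["detected"] = df["cq"].notna()
    df["detected"] = df["detected"].astype(bool)
    return df


def write_electropherogram_tsv(trace: Electropherogram, path: str | Path) -> None:
    pd.DataFrame(
        {"size_nt": trace.size_axis, "fluorescence": trace.fluorescence}
    ).to_csv(path, sep="\t", index=False)


def read_electropherogram_tsv(path: str | Path, sample_id: str = "") -> Electropherogram:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("size_nt", "fluorescence"):
        if col not in df.columns:
            raise FormatError(f"electropherogram {path} missing column {col!r}")
    return Electropherogram(
        size_axis=df["size_nt"].to_numpy(dtype=float),
        fluorescence=df["fluorescence"].to_numpy(dtype=float),
        sample_id=sample_id or Path(path).stem,
    )


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "sample" not in df.columns:
        raise FormatError(f"sample sheet {path} missing 'sample' column")
    if "is_empty_control" in df.columns:
        df["is_empty_control"] = df["is_empty_control"].astype(bool)
    return df


def write_sites_tsv(calls, path: str | Path) -> None:
    """Assigned cleavage sites as a TSV (one row per dip)."""
    rows = [
        {
            "transcript_id": c.transcript_id,
            "dip_start": c.start,
            "dip_end": c.end,
            "depth_ratio": round(c.depth_ratio, 6),
            "position": "" if c.position is None else c.position,
            "dinucleotide": c.dinucleotide or "",
            "context": c.context or "",
        }
        for c in sorted(calls, key=lambda c: (c.transcript_id, c.start))
    ]
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "dip_start",
            "dip_end",
            "depth_ratio",
            "position",
            "dinucleotide",
            "context",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["position"] = pd.to_numeric(df["position"], errors="coerce").astype("Int64")
    return df


def write_pfm_tsv(summary, path: str | Path) -> None:
    out = summary.pfm.copy()
    out["information_bits"] = summary.information_content
    out.to_csv(path, sep="\t")


def write_fold_change_tsv(table: pd.DataFrame, path: str | Path, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for k, v in header.items():
                fh.write(f"# {k}: {v}\n")
        table.to_csv(fh, sep="\t", index_label="gene_id")
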