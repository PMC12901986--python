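"""Synthetic transcriptome construction.

A transcriptome is a list of transcript records (id, RNA sequence, biotype,
per-cell abundance) plus the known relative concentrations of the spike-in
controls. Spike-ins emulate a commercial 92-member mix with concentrations
log-spaced over a wide dynamic range; they are added after RNA isolation in
the modelled protocol and therefore are never subject to cleavage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .._rng import rng_from_seed
from ..errors import ValidationError

__all__ = [
    "BIOTYPES",
    "TranscriptRecord",
    "Transcriptome",
    "largest_remainder_counts",
    "build_transcriptome",
]

BIOTYPES = ("protein_coding", "mito_mRNA", "nuclear_ncRNA", "spike_in")

_ALPHABET = np.array(list("ACGU"))

#: Defaults for the spike-in mix emulation: 92 species, concentrations
#: log2-spaced over a 2**20 dynamic range (single-mix analog).
DEFAULT_N_SPIKEINS = 92
DEFAULT_SPIKE_DYNAMIC_RANGE = 2.0**20


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    sequence: str
    biotype: str
    abundance: float

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"unknown biotype {self.biotype!r}")
        if not self.sequence:
            raise ValidationError(f"transcript {self.id!r} has empty sequence")
        if set(self.sequence) - set("ACGU"):
            raise ValidationError(
                f"transcript {self.id!r} contains non-ACGU characters"
            )
        if not (self.abundance >= 0):
            raise ValidationError(
                f"transcript {self.id!r} has negative abundance {self.abundance}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Transcriptome:
    transcripts: list[TranscriptRecord]
    spike_in_concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValidationError("transcript ids are not unique")
        spike_ids = {t.id for t in self.transcripts if t.biotype == "spike_in"}
        conc_ids = set(self.spike_in_concentrations)
        if spike_ids != conc_ids:
            raise ValidationError(
                "spike_in transcripts and spike_in_concentrations disagree: "
                f"missing={sorted(spike_ids - conc_ids)}, "
                f"extra={sorted(conc_ids - spike_ids)}"
            )
        for conc in self.spike_in_concentrations.values():
            if not (conc > 0):
                raise ValidationError("spike-in concentrations must be > 0")

    def __len__(self) -> int:
        return len(self.transcripts)

    def get(self, transcript_id: str) -> TranscriptRecord:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(transcript_id)

    @property
    def sequences(self) -> dict[str, str]:
        return {t.id: t.sequence for t in self.transcripts}

    @property
    def lengths(self) -> dict[str, int]:
        return {t.id: t.length for t in self.transcripts}

    def by_biotype(self, biotype: str) -> list[TranscriptRecord]:
        return [t for t in self.transcripts if t.biotype == biotype]


def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` items to classes by the largest-remainder method."""
    quotas = {k: n * f for k, f in fractions.items()}
    counts = {k: math.floor(q) for k, q in quotas.items()}
    shortfall = n - sum(counts.values())
    # ties broken by class name for determinism
    order = sorted(quotas, key=lambda k: (counts[k] - quotas[k], k))
    for k in order[:shortfall]:
        counts[k] += 1
    return counts


def build_transcriptome(
    n_transcripts: int,
    biotype_fractions: dict[str, float],
    abundance_lognormal_params: tuple[float, float] = (math.log(100.0), 1.0),
    seq_length_range: tuple[int, int] = (500, 2000),
    n_spikeins: int | None = None,
    seed: int = 0,
    spike_dynamic_range: float = DEFAULT_SPIKE_DYNAMIC_RANGE,
    spike_abundance_scale: float = 0.002,
) -> Transcriptome:
    """Build a random transcriptome with the requested class composition.

    Parameters
    ----------
    n_transcripts:
        Total number of transcripts, apportioned over the biotype classes
        by largest-remainder rounding of ``biotype_fractions``.
    biotype_fractions:
        Mapping biotype -> fraction; must sum to 1 within 1e-6.
    abundance_lognormal_params:
        ``(mu, sigma)`` of the natural-log normal from which non-spike
        abundances (molecules per cell) are drawn.
    seq_length_range:
        Inclusive bounds for uniform random sequence lengths.
    n_spikeins:
        Overrides the spike-in count implied by ``biotype_fractions``
        (others keep their largest-remainder counts).
    spike_dynamic_range:
        Ratio between the most and least concentrated spike-in; the
        concentrations are log-spaced across it.
    spike_abundance_scale:
        Multiplier converting spike concentration to the abundance slot.

    Deterministic for a fixed seed.
    """
    if n_transcripts <= 0:
        raise ValidationError("n_transcripts must be > 0")
    unknown = set(biotype_fractions) - set(BIOTYPES)
    if unknown:
        raise ValidationError(f"unknown biotypes in fractions: {sorted(unknown)}")
    total = sum(biotype_fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"biotype fractions sum to {total}, expected 1")
    lo, hi = seq_length_range
    if not (0 < lo <= hi):
        raise ValidationError(f"invalid seq_length_range {seq_length_range}")

    counts = largest_remainder_counts(biotype_fractions, n_transcripts)
    if n_spikeins is not None:
        counts["spike_in"] = int(n_spikeins)

    rng = rng_from_seed(seed)
    mu, sigma = abundance_lognormal_params

    transcripts: list[TranscriptRecord] = []
    concentrations: dict[str, float] = {}
    prefixes = {
        "protein_coding": "PC",
        "mito_mRNA": "MT",
        "nuclear_ncRNA": "NC",
        "spike_in": "SPIKE",
    }
    n_spike = counts.get("spike_in", 0)
    if n_spike == 1:
        spike_conc = np.array([1.0])
    else:
        spike_conc = np.logspace(
            0.0, math.log10(spike_dynamic_range), max(n_spike, 1)
        )
    spike_i = 0
    for biotype in BIOTYPES:
        for i in range(counts.get(biotype, 0)):
            tid = f"{prefixes[biotype]}_{i + 1:04d}"
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(_ALPHABET[rng.integers(0, 4, size=length)])
            if biotype == "spike_in":
                conc = float(spike_conc[spike_i])
                spike_i += 1
                concentrations[tid] = conc
                abundance = conc * spike_abundance_scale
            else:
                abundance = float(rng.lognormal(mu, sigma))
            transcripts.append(TranscriptRecord(tid, seq, biotype, abundance))

    return Transcriptome(transcripts, concentrations)
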