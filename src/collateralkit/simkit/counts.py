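"""Negative-binomial count matrix simulation with spike-in anchoring.

Treated-sample gene means are scaled by ``2 ** log2fc`` where the expected
log2 fold change is linear in log10 abundance plus class and per-gene
offsets. Spike-in rows always use concentration x library scale — they are
added after isolation and never depleted, which is what makes them a valid
normalization anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import rng_from_seed
from ..errors import ValidationError
from ..spikenorm import CountMatrix
from .transcriptome import Transcriptome

__all__ = ["DepletionSpec", "simulate_count_matrix", "expected_log2fc"]


@dataclass
class DepletionSpec:
    """Expected log2FC per gene: ``a + b * log10(abundance) + offsets``."""

    intercept: float = 0.0
    log10_slope: float = 0.0
    class_offsets: dict[str, float] = field(default_factory=dict)
    gene_offsets: dict[str, float] = field(default_factory=dict)


def expected_log2fc(tx: Transcriptome, spec: DepletionSpec) -> pd.Series:
    """Per-gene expected treated-vs-control log2FC (spike-ins always 0)."""
    values = {}
    for t in tx.transcripts:
        if t.biotype == "spike_in":
            values[t.id] = 0.0
            continue
        lfc = spec.intercept
        if spec.log10_slope and t.abundance > 0:
            lfc += spec.log10_slope * np.log10(t.abundance)
        lfc += spec.class_offsets.get(t.biotype, 0.0)
        lfc += spec.gene_offsets.get(t.id, 0.0)
        values[t.id] = lfc
    return pd.Series(values, name="log2fc")


def expected_means(
    tx: Transcriptome,
    spec: DepletionSpec,
    design: dict[str, str],
    library_scales: dict[str, float],
    treated_conditions: tuple[str, ...] = ("targeting",),
    spike_scale: float = 1.0,
) -> pd.DataFrame:
    """Noise-free expected counts per gene and sample."""
    lfc = expected_log2fc(tx, spec)
    cols = {}
    for sample, condition in design.items():
        scale = library_scales[sample]
        treated = condition in treated_conditions
        col = {}
        for t in tx.transcripts:
            if t.biotype == "spike_in":
                col[t.id] = tx.spike_in_concentrations[t.id] * scale * spike_scale
            else:
                mu = t.abundance * scale
                if treated:
                    mu *= 2.0 ** lfc[t.id]
                col[t.id] = mu
        cols[sample] = col
    return pd.DataFrame(cols)


def simulate_count_matrix(
    tx: Transcriptome,
    depletion_spec: DepletionSpec,
    design: dict[str, str],
    library_scales: dict[str, float] | None = None,
    dispersion: float = 0.05,
    seed: int = 0,
    treated_conditions: tuple[str, ...] = ("targeting",),
    spike_scale: float = 1.0,
    timepoint: float | None = None,
) -> CountMatrix:
    """Draw a genes x samples count matrix.

    ``design`` maps sample id -> condition; samples whose condition is in
    ``treated_conditions`` receive the depletion. ``library_scales``
    default to 1 for every sample. Counts are NB with the given
    dispersion (variance = mu + dispersion * mu^2).
    """
    if not design:
        raise ValidationError("design must assign at least one sample")
    if library_scales is None:
        library_scales = {s: 1.0 for s in design}
    missing = set(design) - set(library_scales)
    if missing:
        raise ValidationError(f"library_scales missing for samples: {sorted(missing)}")
    if any(v <= 0 for v in library_scales.values()):
        raise ValidationError("library_scales must be > 0")
    if not (dispersion > 0):
        raise ValidationError("dispersion must be > 0")

    mu = expected_means(
        tx, depletion_spec, design, library_scales, treated_conditions, spike_scale
    )
    rng = rng_from_seed(seed)
    n = 1.0 / dispersion
    mu_arr = mu.to_numpy(dtype=float)
    p = n / (n + mu_arr)
    counts = np.where(mu_arr > 0, rng.negative_binomial(n, np.minimum(p, 1.0)), 0)
    counts_df = pd.DataFrame(counts, index=mu.index, columns=mu.columns)

    biotypes = pd.Series(
        {t.id: t.biotype for t in tx.transcripts}, name="biotype"
    ).reindex(counts_df.index)
    spike = biotypes == "spike_in"
    spike.name = "spike_in"
    samples = pd.DataFrame(
        {
            "condition": pd.Series(design),
            "timepoint": timepoint,
        }
    )
    return CountMatrix(
        counts=counts_df, spike_in=spike, samples=samples, biotypes=biotypes
    )
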