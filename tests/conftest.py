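import numpy as np
import pytest

from collateralkit import simkit

FRACTIONS = {
    "protein_coding": 0.80,
    "mito_mRNA": 0.05,
    "nuclear_ncRNA": 0.10,
    "spike_in": 0.05,
}


@pytest.fixture(scope="session")
def small_transcriptome() -> simkit.Transcriptome:
    return simkit.build_transcriptome(
        n_transcripts=60,
        biotype_fractions=FRACTIONS,
        seq_length_range=(400, 1200),
        seed=42,
    )


@pytest.fixture(scope="session")
def default_model() -> simkit.CleavageModel:
    return simkit.CleavageModel()


def interval_jaccard(a: list[tuple[int, int]], b: list[tuple[int, int]], n: int) -> float:
    """Jaccard index of two interval sets over [0, n)."""
    mask_a = np.zeros(n, dtype=bool)
    mask_b = np.zeros(n, dtype=bool)
    for lo, hi in a:
        mask_a[lo:hi] = True
    for lo, hi in b:
        mask_b[lo:hi] = True
    union = (mask_a | mask_b).sum()
    if union == 0:
        return 1.0
    return (mask_a & mask_b).sum() / union
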