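"""Electropherogram trace synthesis from a fragment pool.

Each fragment-length class contributes a Gaussian peak in log-size,
weighted by its total mass (count x length); ribosomal RNA peaks of fixed
size and mass are added on top. The trace is a mass density over size, so
the total trapezoidal AUC is proportional to the total RNA mass and
cutting long molecules into sub-window fragments moves area into the
degradation window without changing the total.
"""

from __future__ import annotations

import numpy as np

from .._rng import rng_from_seed
from ..assays import Electropherogram
from ..errors import ValidationError
from .cleavage import FragmentPool

__all__ = ["simulate_electropherogram", "DEFAULT_RRNA_PEAKS", "default_size_grid"]

#: (size nt, relative mass) of the two large ribosomal peaks in an intact
#: total RNA profile.
DEFAULT_RRNA_PEAKS: list[tuple[float, float]] = [(1869.0, 5.0e5), (5070.0, 1.0e6)]


def default_size_grid(lo: float = 25.0, hi: float = 8000.0, n: int = 1200) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def simulate_electropherogram(
    pool: FragmentPool,
    rRNA_peaks: list[tuple[float, float]] | None = None,
    peak_width: float = 0.04,
    grid: np.ndarray | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    sample_id: str = "",
) -> Electropherogram:
    """Render a fluorescence-vs-size trace for a fragment pool.

    ``peak_width`` is the Gaussian sigma in natural-log size units.
    Additive Gaussian noise (``noise_sd``, trace units) is optional and
    clipped at zero so the trace stays non-negative.
    """
    if rRNA_peaks is None:
        rRNA_peaks = DEFAULT_RRNA_PEAKS
    if grid is None:
        grid = default_size_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValidationError("grid must be strictly increasing with >= 2 points")
    if peak_width <= 0:
        raise ValidationError("peak_width must be > 0")

    lengths = np.array([f.length for f in pool.fragments], dtype=float)
    sizes_list: list[np.ndarray] = []
    masses_list: list[np.ndarray] = []
    if lengths.size:
        uniq, counts = np.unique(lengths, return_counts=True)
        sizes_list.append(uniq)
        masses_list.append(counts * uniq)  # mass-weighted: count x length
    if rRNA_peaks:
        sizes_list.append(np.array([s for s, _ in rRNA_peaks], dtype=float))
        masses_list.append(np.array([m for _, m in rRNA_peaks], dtype=float))
    log_grid = np.log(grid)
    trace = np.zeros_like(grid)
    if sizes_list:
        sizes = np.concatenate(sizes_list)
        masses = np.concatenate(masses_list)
        # mass density over size: integrates (trapezoid over the grid) to
        # the total mass of peaks inside the grid support
        z = (log_grid[None, :] - np.log(sizes)[:, None]) / peak_width
        kernel = np.exp(-0.5 * z**2) / (peak_width * np.sqrt(2.0 * np.pi) * grid)
        trace = masses @ kernel
    if noise_sd > 0:
        rng = rng_from_seed(seed)
        trace = np.clip(trace + rng.normal(0.0, noise_sd, size=trace.size), 0.0, None)
    return Electropherogram(size_axis=grid, fluorescence=trace, sample_id=sample_id)
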