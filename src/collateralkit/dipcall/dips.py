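"""Coverage-dip detection.

Recurrent cleavage shows up as a localized depression in per-base depth,
typically 10-20 nt wide. After running-median smoothing, a dip is a
maximal run of positions whose smoothed depth falls below a threshold
fraction of the local baseline (the median depth of flanking windows),
subject to a width window and an exclusion zone at the transcript ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from ..errors import LowCoverageError, ValidationError
from .coverage import CoverageProfile

__all__ = ["DipCall", "detect_dips", "DEFAULT_DIP_PARAMS"]

logger = logging.getLogger(__name__)

#: Defaults for the dip caller; all exposed as keyword arguments.
DEFAULT_DIP_PARAMS = dict(
    smooth_window=5,
    baseline_window=50,
    depth_ratio_threshold=0.5,
    width_range=(8, 30),
    edge_exclusion=25,
    min_mean_depth=20.0,
    merge_gap=3,
)


@dataclass(frozen=True)
class DipCall:
    """A detected coverage dip, optionally with an assigned cleavage U."""

    transcript_id: str
    start: int
    end: int  # half-open
    depth_ratio: float  # dip minimum / local baseline
    position: int | None = None  # index of the assigned uracil
    context: str | None = None  # sequence window around the U
    dinucleotide: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start

    def with_position(self, position, context=None, dinucleotide=None) -> "DipCall":
        return replace(
            self, position=position, context=context, dinucleotide=dinucleotide
        )


def _flank_median(
    s: np.ndarray, lo: int, hi: int, baseline_window: int
) -> float:
    """Median of the smoothed depth over windows flanking [lo, hi)."""
    left = s[max(0, lo - baseline_window) : lo]
    right = s[hi : hi + baseline_window]
    flanks = np.concatenate([left, right])
    if flanks.size == 0:
        return float("nan")
    return float(np.median(flanks))


def detect_dips(
    profile: CoverageProfile,
    smooth_window: int = 5,
    baseline_window: int = 50,
    depth_ratio_threshold: float = 0.5,
    width_range: tuple[int, int] = (8, 30),
    edge_exclusion: int = 25,
    min_mean_depth: float = 20.0,
    merge_gap: int = 3,
) -> list[DipCall]:
    """Call coverage dips on one transcript.

    Raises :class:`LowCoverageError` when the transcript mean depth is
    below ``min_mean_depth`` (callers batching many transcripts should
    catch it and skip with a log entry).
    """
    if not (0 < depth_ratio_threshold < 1):
        raise ValidationError("depth_ratio_threshold must be in (0, 1)")
    w_min, w_max = width_range
    if not (0 < w_min <= w_max):
        raise ValidationError(f"invalid width_range {width_range}")
    if profile.mean_depth < min_mean_depth:
        raise LowCoverageError(
            f"transcript {profile.transcript_id!r}: mean depth "
            f"{profile.mean_depth:.1f} < {min_mean_depth}"
        )

    depth = profile.depth.astype(float)
    n = depth.size
    smoothed = median_filter(depth, size=smooth_window, mode="nearest")

    # per-position baseline: median of two windows offset by a guard of
    # the maximum dip width, so a dip never contaminates its own baseline
    guard = w_max
    baseline = np.full(n, np.nan)
    idx = np.arange(n)
    left_start = np.maximum(0, idx - guard - baseline_window)
    # vectorizing an irregular median is awkward; windows are short so a
    # strided pass is fine at transcript scale
    pad = np.concatenate(
        [np.full(guard + baseline_window, np.nan), smoothed, np.full(guard + baseline_window, np.nan)]
    )
    offset = guard + baseline_window
    windows_left = np.lib.stride_tricks.sliding_window_view(
        pad, baseline_window
    )[idx + offset - guard - baseline_window]
    windows_right = np.lib.stride_tricks.sliding_window_view(
        pad, baseline_window
    )[idx + offset + guard + 1]
    both = np.concatenate([windows_left, windows_right], axis=1)
    baseline = np.nanmedian(both, axis=1)
    del left_start

    with np.errstate(invalid="ignore"):
        below = smoothed < depth_ratio_threshold * baseline
    below &= np.isfinite(baseline)

    # maximal runs of below-threshold positions
    runs = _runs(below)
    runs = _merge_runs(runs, merge_gap)

    calls: list[DipCall] = []
    for lo, hi in runs:
        width = hi - lo
        if not (w_min <= width <= w_max):
            continue
        if lo < edge_exclusion or hi > n - edge_exclusion:
            continue
        run_baseline = _flank_median(smoothed, lo, hi, baseline_window)
        if not np.isfinite(run_baseline) or run_baseline <= 0:
            continue
        ratio = float(smoothed[lo:hi].min() / run_baseline)
        if ratio >= depth_ratio_threshold:
            continue
        calls.append(
            DipCall(
                transcript_id=profile.transcript_id,
                start=int(lo),
                end=int(hi),
                depth_ratio=ratio,
            )
        )
    return calls


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(
    runs: list[tuple[int, int]], merge_gap: int
) -> list[tuple[int, int]]:
    """Merge adjacent runs separated by fewer than ``merge_gap`` positions."""
    if not runs:
        return []
    merged = [runs[0]]
    for lo, hi in runs[1:]:
        plo, phi = merged[-1]
        if lo - phi < merge_gap:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged
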