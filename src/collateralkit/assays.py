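"""Bulk degradation readouts.

Electropherogram traces (fluorescence vs fragment size) are quantified by
trapezoidal area under the curve: total AUC for loading normalization and
regional AUC for the degradation-fragment window. In vitro cleavage rates
are the least-squares slope over the initial linear rise of a
fluorescence time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "Electropherogram",
    "FluorescenceSeries",
    "trace_total_auc",
    "normalize_traces",
    "region_auc",
    "fluorescence_slope",
    "DEFAULT_DEGRADATION_REGION",
]

#: Default degradation-fragment window (nt): below the small ribosomal
#: subunit peak, above primer/adapter sizes. Configurable per run.
DEFAULT_DEGRADATION_REGION = (200.0, 1700.0)


@dataclass(frozen=True)
class Electropherogram:
    size_axis: np.ndarray  # nucleotides, strictly increasing
    fluorescence: np.ndarray  # arbitrary units
    sample_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_axis", np.asarray(self.size_axis, dtype=float))
        object.__setattr__(
            self, "fluorescence", np.asarray(self.fluorescence, dtype=float)
        )
        if self.size_axis.ndim != 1 or self.size_axis.size < 2:
            raise ValidationError("size axis needs at least 2 points")
        if self.size_axis.size != self.fluorescence.size:
            raise ValidationError("size axis and fluorescence lengths differ")
        if not np.all(np.diff(self.size_axis) > 0):
            raise ValidationError("size axis must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValidationError("fluorescence contains non-finite values")


@dataclass(frozen=True)
class FluorescenceSeries:
    time: np.ndarray  # minutes
    signal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.time.size < 2 or self.time.size != self.signal.size:
            raise ValidationError("time and signal must have equal length >= 2")
        if not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be increasing")


def trace_total_auc(trace: Electropherogram) -> float:
    """Trapezoidal integral of the full trace (units x nt)."""
    return float(np.trapezoid(trace.fluorescence, trace.size_axis))


def normalize_traces(traces: list[Electropherogram]) -> list[Electropherogram]:
    """Equalize loading: divide each trace by its own total AUC and
    multiply by the mean total AUC over all input traces.

    Every output trace then integrates to the input mean AUC.
    """
    if not traces:
        return []
    aucs = [trace_total_auc(t) for t in traces]
    for t, a in zip(traces, aucs):
        if a <= 0:
            raise ValidationError(
                f"trace {t.sample_id!r} has non-positive total AUC ({a}); "
                "cannot normalize"
            )
    mean_auc = float(np.mean(aucs))
    return [
        replace(t, fluorescence=t.fluorescence * (mean_auc / a))
        for t, a in zip(traces, aucs)
    ]


def region_auc(
    trace: Electropherogram, region: tuple[float, float]
) -> tuple[float, float]:
    """Trapezoidal integral restricted to a size interval.

    Region boundaries falling between grid points are handled by linear
    interpolation. Returns ``(area, fraction_of_total)``; a region outside
    the axis support yields area 0 with a warning.
    """
    lo, hi = region
    if not (lo < hi):
        raise ValidationError(f"invalid region {region}")
    x, y = trace.size_axis, trace.fluorescence
    total = float(np.trapezoid(y, x))
    if hi <= x[0] or lo >= x[-1]:
        warnings.warn(
            f"region [{lo}, {hi}] outside axis support "
            f"[{x[0]}, {x[-1]}]; area is 0"
        )
        return 0.0, 0.0
    lo_c, hi_c = max(lo, float(x[0])), min(hi, float(x[-1]))
    inside = (x > lo_c) & (x < hi_c)
    xs = np.concatenate(([lo_c], x[inside], [hi_c]))
    ys = np.interp(xs, x, y)
    area = float(np.trapezoid(ys, xs))
    fraction = area / total if total != 0 else 0.0
    return area, fraction


def fluorescence_slope(
    series: FluorescenceSeries,
    window: tuple[float, float] | None = None,
    rms_tolerance: float = 0.02,
) -> float:
    """Initial cleavage rate (signal units per minute).

    With ``window=None`` the initial linear stretch is selected
    automatically: the longest prefix of at least 3 points whose residual
    RMS around its own least-squares line is below ``rms_tolerance`` times
    the full signal range. An explicit ``(t0, t1)`` window overrides the
    rule. Returns the least-squares slope over the selected points.
    """
    t, y = series.time, series.signal
    if t.size < 3:
        raise ValidationError("need at least 3 points to estimate a slope")
    if window is not None:
        t0, t1 = window
        mask = (t >= t0) & (t <= t1)
        if mask.sum() < 3:
            raise ValidationError(
                f"window [{t0}, {t1}] selects fewer than 3 points"
            )
        return _ls_slope(t[mask], y[mask])

    signal_range = float(np.ptp(y))
    if signal_range == 0.0:
        return 0.0
    best_end = None
    for end in range(3, t.size + 1):
        slope, intercept = _ls_fit(t[:end], y[:end])
        resid = y[:end] - (intercept + slope * t[:end])
        rms = float(np.sqrt(np.mean(resid**2)))
        if rms < rms_tolerance * signal_range:
            best_end = end
    if best_end is None:
        raise ValidationError(
            "no initial prefix of >= 3 points is linear within tolerance"
        )
    return _ls_slope(t[:best_end], y[:best_end])


def _ls_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    return slope, float(ym - slope * xm)


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    return _ls_fit(x, y)[0]
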