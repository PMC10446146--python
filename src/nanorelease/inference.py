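"""Chamber source-rate estimation from concentration time series.

In a sealed chamber the mass balance reduces to V dC/dt = G, so the source
rate follows from the time derivative of the concentration. The estimator
used here:

1. mask intervals known to be perturbed (e.g. the brief external-sampling
   windows that pull laboratory air into the chamber),
2. average the series into non-overlapping blocks (default 15 min),
3. take finite differences between consecutive blocks, never across a
   masked gap,
4. report mean +/- sample standard deviation of the differences, and an
   upper-range emission rate G_upper = (mean + k_sigma * sd) * V.

Because consecutive finite differences telescope, the mean derivative is
driven by the endpoints and is an efficient slope estimate for a linear
trend; the standard deviation captures window-to-window fluctuation and
feeds the conservative upper range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConcentrationSeries",
    "ExclusionIntervals",
    "DerivativeStats",
    "EmissionBound",
    "EmptySeriesError",
    "mask_series",
    "block_average",
    "derivative_stats",
    "emission_bound",
]

#: cm3 per m3 — converts a chamber volume in m3 to the denominator volume
#: of a number concentration in 1/cm3.
_CM3_PER_M3 = 1e6


class EmptySeriesError(ValueError):
    """Raised when masking or averaging leaves no usable data."""


@dataclass(frozen=True)
class ConcentrationSeries:
    """A timestamped concentration series from one instrument, one metric.

    timestamps_s: strictly increasing sample times (s).
    values: concentrations, 1/cm3 for metric "number", ng/m3 for "mass".
    segments: integer label per sample; finite differences are only taken
        within a segment, so masked gaps never contribute a derivative.
    window_s: block length if this series is block-averaged, else None.
    """

    timestamps_s: np.ndarray
    values: np.ndarray
    metric: str = "number"
    instrument_label: str = ""
    segments: np.ndarray | None = None
    window_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("timestamps and values must be 1-D and equal length")
        if t.size == 0:
            raise EmptySeriesError("series has no samples")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("concentrations must be >= 0")
        if self.metric not in ("number", "mass"):
            raise ValueError("metric must be 'number' or 'mass'")
        seg = self.segments
        seg = np.zeros(t.size, dtype=int) if seg is None else np.asarray(seg, dtype=int)
        if seg.shape != t.shape:
            raise ValueError("segments must match timestamps in length")
        object.__setattr__(self, "timestamps_s", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "segments", seg)

    def __len__(self) -> int:
        return self.timestamps_s.size

    @property
    def median_dt_s(self) -> float:
        if len(self) < 2:
            raise ValueError("need >= 2 samples for a sampling interval")
        return float(np.median(np.diff(self.timestamps_s)))


@dataclass(frozen=True)
class ExclusionIntervals:
    """Half-open [start, end) time windows (s) to mask out of a series."""

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if not start < end:
                raise ValueError(f"interval start must precede end: [{start}, {end})")
        object.__setattr__(self, "intervals", self._normalized())

    def _normalized(self) -> tuple[tuple[float, float], ...]:
        """Sort and merge overlapping/adjacent intervals."""
        if not self.intervals:
            return ()
        ordered = sorted(self.intervals)
        merged = [list(ordered[0])]
        for start, end in ordered[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class DerivativeStats:
    """Mean and sample sd of window-to-window concentration derivatives.

    Units are (state unit)/s, i.e. 1/(cm3*s) for number series.
    """

    mean: float
    sd: float
    n_windows: int
    window_length_s: float | None
    metric: str = "number"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_windows < 2:
            raise ValueError("need >= 2 derivative samples")


@dataclass(frozen=True)
class EmissionBound:
    """Point estimate and k-sigma upper range of the chamber source rate."""

    point: float
    upper: float
    k_sigma: float
    chamber_volume_m3: float
    unit: str = "1/s"


def mask_series(series: ConcentrationSeries, excl: ExclusionIntervals) -> ConcentrationSeries:
    """Drop samples inside any exclusion interval, recording gap locations.

    Gap locations are recorded as segment boundaries so later derivatives
    never span a gap. Masking everything raises EmptySeriesError.
    """
    if not excl.intervals:
        return series
    t = series.timestamps_s
    keep = np.ones(t.size, dtype=bool)
    for start, end in excl.intervals:
        keep &= ~((t >= start) & (t < end))
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        raise EmptySeriesError("exclusion intervals mask the entire series")
    dropped_between = np.diff(idx) > 1
    seg_changed = np.diff(series.segments[idx]) != 0
    new_seg = np.concatenate(([0], np.cumsum(dropped_between | seg_changed)))
    return replace(
        series,
        timestamps_s=t[idx],
        values=series.values[idx],
        segments=new_seg,
    )


def block_average(series: ConcentrationSeries, window_s: float) -> ConcentrationSeries:
    """Average into non-overlapping blocks of ``window_s`` seconds.

    Blocks are anchored at the first timestamp. Each output point is the
    mean of the samples in its block, timestamped at their mean time (the
    block centre for symmetric sampling). Blocks containing samples from
    more than one segment — i.e. spanning a masked gap — are dropped, and
    non-adjacent surviving blocks start new segments.
    """
    if window_s <= 0:
        raise ValueError("window must be > 0")
    if len(series) >= 2 and window_s < 2.0 * series.median_dt_s:
        raise ValueError(
            f"window {window_s} s is shorter than twice the median sampling "
            f"interval {series.median_dt_s} s"
        )
    t = series.timestamps_s
    block = np.floor((t - t[0]) / window_s).astype(np.int64)
    n_blocks = int(block[-1]) + 1
    counts = np.bincount(block, minlength=n_blocks)
    sum_v = np.bincount(block, weights=series.values, minlength=n_blocks)
    sum_t = np.bincount(block, weights=t, minlength=n_blocks)
    seg_min = np.full(n_blocks, np.iinfo(np.int64).max, dtype=np.int64)
    seg_max = np.full(n_blocks, np.iinfo(np.int64).min, dtype=np.int64)
    np.minimum.at(seg_min, block, series.segments)
    np.maximum.at(seg_max, block, series.segments)
    ok = (counts > 0) & (seg_min == seg_max)
    if not np.any(ok):
        raise EmptySeriesError("no usable blocks after averaging")
    blocks = np.nonzero(ok)[0]
    # new segment wherever surviving blocks are non-adjacent or the
    # underlying segment changed
    breaks = (np.diff(blocks) > 1) | (np.diff(seg_min[blocks]) != 0)
    new_seg = np.concatenate(([0], np.cumsum(breaks)))
    return replace(
        series,
        timestamps_s=sum_t[blocks] / counts[blocks],
        values=sum_v[blocks] / counts[blocks],
        segments=new_seg,
        window_s=window_s,
    )


def derivative_stats(series: ConcentrationSeries) -> DerivativeStats:
    """Finite differences between consecutive same-segment points.

    Returns their mean, sample (n-1) standard deviation and count.
    """
    if len(series) < 3:
        raise ValueError("need >= 3 points for derivative statistics")
    t = series.timestamps_s
    v = series.values
    same_segment = np.diff(series.segments) == 0
    d = np.diff(v)[same_segment] / np.diff(t)[same_segment]
    if d.size < 2:
        raise ValueError("fewer than 2 usable differences (gaps too dense)")
    return DerivativeStats(
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=1)),
        n_windows=int(d.size),
        window_length_s=series.window_s,
        metric=series.metric,
    )


def emission_bound(
    stats: DerivativeStats, chamber_volume_m3: float, k_sigma: float = 1.0
) -> EmissionBound:
    """Source rate via the sealed-chamber balance G = V * dC/dt.

    point = mean * V; upper = (mean + k_sigma * sd) * V, floored at zero
    (an emission rate is non-negative by definition; a negative upper range
    indicates net loss, reported as 0). For number series the volume enters
    in cm3 so the rate is particles/s; for mass series in m3, giving ng/s.
    """
    if chamber_volume_m3 <= 0:
        raise ValueError("chamber volume must be > 0")
    if stats.metric == "number":
        v_state = chamber_volume_m3 * _CM3_PER_M3
        unit = "1/s"
    else:
        v_state = chamber_volume_m3
        unit = "ng/s"
    point = stats.mean * v_state
    upper = max((stats.mean + k_sigma * stats.sd) * v_state, 0.0)
    return EmissionBound(
        point=point,
        upper=upper,
        k_sigma=k_sigma,
        chamber_volume_m3=chamber_volume_m3,
        unit=unit,
    )
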