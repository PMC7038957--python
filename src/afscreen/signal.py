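"""Signal conditioning, R-peak detection and RR-interval extraction.

The default smoother is the 5-tap moving average b = [0.2, 0.2, 0.2, 0.2,
0.2], a = [1] — a fourth-order FIR with unit DC gain and a 2-sample group
delay.  Because the delay is constant it cancels in RR differences, so no
delay compensation is applied.  Peaks are found by topographic prominence,
which is invariant to constant offsets, with a physiologic refractory
spacing (0.25 s ~ 240 bpm upper bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.signal import find_peaks, lfilter

from .core import RRSeries, Signal

__all__ = ["FilterSpec", "PeakList", "smooth", "detect_r_peaks", "compute_rr", "window_rr"]


@dataclass(frozen=True)
class FilterSpec:
    """Rational transfer function coefficients (numerator b, denominator a)."""

    b: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    a: tuple = (1.0,)

    def __post_init__(self) -> None:
        if len(self.a) == 0 or self.a[0] == 0:
            raise ValueError("a[0] must be non-zero")

    @property
    def order(self) -> int:
        return max(len(self.b), len(self.a)) - 1


@dataclass(frozen=True)
class PeakList:
    """Detected R-peak sample indices (strictly increasing)."""

    indices: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


def smooth(signal: Signal, spec: FilterSpec = FilterSpec()) -> Signal:
    """Causal direct-form filtering with zero initial conditions.

    y[n] = sum_i b[i] x[n-i] - sum_j a[j] y[n-j], a normalized by a[0];
    output length equals input length.
    """
    y = lfilter(np.asarray(spec.b, float), np.asarray(spec.a, float), signal.samples)
    return Signal(y, signal.sampling_rate)


def detect_r_peaks(
    signal: Signal,
    min_distance: float = 0.25,
    min_prominence: float = 0.4,
) -> PeakList:
    """Detect R peaks as prominent local maxima.

    A candidate must have topographic prominence of at least
    ``min_prominence`` times the robust signal range (99th percentile
    minus median) and be at least ``min_distance`` seconds from any
    higher accepted peak (the higher peak wins a conflict).

    A flat or empty signal yields an empty peak list.
    """
    x = signal.samples
    if x.size < 3:
        return PeakList(np.array([], dtype=int), signal.sampling_rate)
    robust_range = float(np.percentile(x, 99) - np.median(x))
    if robust_range <= 0:
        return PeakList(np.array([], dtype=int), signal.sampling_rate)
    distance = max(int(round(min_distance * signal.sampling_rate)), 1)
    peaks, _ = find_peaks(x, prominence=min_prominence * robust_range, distance=distance)
    return PeakList(peaks, signal.sampling_rate)


def compute_rr(peaks: PeakList) -> RRSeries:
    """RR intervals in seconds from consecutive peak indices."""
    if len(peaks) < 2:
        raise ValueError("need at least two peaks to form an RR interval")
    rr = np.diff(peaks.indices) / peaks.sampling_rate
    return RRSeries(rr)


def window_rr(
    rr: RRSeries,
    window_len: int = 102,
    step: int | None = None,
) -> List[RRSeries]:
    """Split an RR series into consecutive fixed-length windows.

    The trailing remainder shorter than ``window_len`` is dropped; a
    series shorter than one window yields an empty list.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if step is None:
        step = window_len
    if step < 1:
        raise ValueError("step must be >= 1")
    out: List[RRSeries] = []
    values = rr.values
    for start in range(0, len(values) - window_len + 1, step):
        out.append(RRSeries(values[start : start + window_len], label=rr.label))
    return out
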