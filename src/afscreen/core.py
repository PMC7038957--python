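"""Core data containers shared across the pipeline.

The central currency of the framework is the RR-interval series: the
sequence of times (in seconds) between consecutive R peaks of an ECG.
Everything upstream (chart digitization, filtering, peak detection) exists
to produce one, and everything downstream (calibration, symbolic recurrence
features, the NS/AF classifier) consumes one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Recognized rhythm labels.
LABEL_NS = "NS"
LABEL_AF = "AF"


@dataclass(frozen=True)
class RRSeries:
    """A series of inter-beat (RR) intervals in seconds.

    Parameters
    ----------
    values
        Positive, finite interval durations, one per beat pair.
    label
        Optional rhythm label, ``"NS"`` (normal sinus), ``"AF"``
        (atrial fibrillation) or ``None`` when unknown.
    """

    values: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("RRSeries requires a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValueError("RR intervals must be finite")
        if np.any(vals <= 0):
            raise ValueError("RR intervals must be strictly positive")
        if self.label not in (None, LABEL_NS, LABEL_AF, "unknown"):
            raise ValueError(f"unknown label {self.label!r}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled one-dimensional waveform."""

    samples: np.ndarray
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("Signal samples must be 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Signal samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class WaveParams:
    """One PQRST component as a gaussian bump.

    ``center`` is the offset of the bump from the R peak, as a fraction of
    the local beat length (negative = before the R peak); ``width`` is the
    gaussian standard deviation in seconds; ``amplitude`` is in mV.
    """

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")


def _default_waves() -> dict:
    # Textbook lead-I morphology: dominant R, small P/T, narrow Q/S notches.
    return {
        "P": WaveParams(amplitude=0.15, center=-0.25, width=0.025),
        "Q": WaveParams(amplitude=-0.10, center=-0.070, width=0.012),
        "R": WaveParams(amplitude=1.20, center=0.0, width=0.020),
        "S": WaveParams(amplitude=-0.25, center=0.070, width=0.012),
        "T": WaveParams(amplitude=0.30, center=0.38, width=0.045),
    }


@dataclass(frozen=True)
class SyntheticECGConfig:
    """Shape parameters of the synthetic single-lead PQRST generator."""

    sampling_rate: float = 300.0  # Hz
    wave_params: dict = field(default_factory=_default_waves)
    noise_sd: float = 0.0  # mV, additive white gaussian noise

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        positive = {k: w for k, w in self.wave_params.items() if w.amplitude > 0}
        r = self.wave_params.get("R")
        if r is None or any(
            w.amplitude >= r.amplitude for k, w in positive.items() if k != "R"
        ):
            raise ValueError("R amplitude must be strictly largest among positive waves")


@dataclass(frozen=True)
class ChartRenderConfig:
    """Geometry and styling of a printed ECG chart.

    Defaults follow the universal clinical chart conventions: 25 mm/s paper
    speed, 10 mm/mV gain, 1 mm fine grid with a bold line every 5 mm.
    """

    dpi: float = 600.0
    paper_speed: float = 25.0  # mm/s
    gain: float = 10.0  # mm/mV
    grid_color: tuple = (255, 182, 193)  # light pink, typical ECG paper
    trace_color: tuple = (0, 0, 0)
    fine_grid_mm: float = 1.0
    bold_grid_mm: float = 5.0
    speck_noise_rate: float = 0.0  # fraction of pixels flipped to specks
    height_mm: float = 40.0  # vertical extent of the strip

    def __post_init__(self) -> None:
        if min(self.dpi, self.paper_speed, self.gain) <= 0:
            raise ValueError("dpi, paper_speed and gain must be positive")
        if tuple(self.grid_color) == tuple(self.trace_color):
            raise ValueError("grid_color must differ from trace_color")
        if not 0 <= self.speck_noise_rate < 1:
            raise ValueError("speck_noise_rate must be in [0, 1)")

    @property
    def px_per_second(self) -> float:
        return self.dpi * self.paper_speed / 25.4

    @property
    def px_per_mv(self) -> float:
        return self.dpi * self.gain / 25.4

    @property
    def px_per_mm(self) -> float:
        return self.dpi / 25.4


def as_rr(values: Sequence[float] | RRSeries, label: Optional[str] = None) -> RRSeries:
    """Coerce a plain sequence to :class:`RRSeries` (pass-through if already one)."""
    if isinstance(values, RRSeries):
        return values
    return RRSeries(np.asarray(values, dtype=float), label=label)
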