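"""Synthetic RR series, PQRST waveforms and rendered chart images.

Normal sinus (NS) rhythm is emulated as a quasi-periodic series: a fixed
mean RR plus a slow sinusoidal modulation (respiratory sinus arrhythmia)
plus small gaussian jitter.  Atrial fibrillation (AF) is emulated as an
"irregularly irregular" series: i.i.d. gamma-distributed intervals with a
large coefficient of variation and no serial structure.  These two regimes
reproduce the qualitative contrast that symbolic recurrence analysis keys
on — structured, repeating ordinal patterns in NS versus patternless
symbol sequences in AF.

The chart renderer draws the waveform on a standard gridded ECG strip
(25 mm/s, 10 mm/mV, 1 mm fine / 5 mm bold grid by default) so the
digitizer can be exercised end to end without any scanned input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image

from .core import ChartRenderConfig, RRSeries, Signal, SyntheticECGConfig

__all__ = [
    "generate_rr_ns",
    "generate_rr_af",
    "synthesize_ecg",
    "render_chart",
    "save_chart",
    "save_rr_csv",
    "load_rr_csv",
]

#: physiologic clipping bounds for synthetic RR intervals, seconds
RR_MIN, RR_MAX = 0.2, 2.0

#: lead-in before the first R peak when synthesizing a waveform, seconds
LEAD_IN_S = 0.4


def generate_rr_ns(
    n: int,
    mean_rr: float = 0.8,
    cv: float = 0.01,
    mod_amp: float = 0.05,
    mod_period: float = 6.0,
    seed: int = 0,
) -> RRSeries:
    """Generate a normal-sinus RR series.

    RR_t = mean_rr + mod_amp * sin(2*pi*t / mod_period) + eps_t with
    gaussian eps of sd cv*mean_rr, clipped below at 0.2 s.

    Parameters
    ----------
    n
        Number of intervals (>= 1).
    mean_rr
        Mean interval in seconds (0.8 s = 75 bpm).
    cv
        Coefficient of variation of the beat-to-beat jitter, restricted
        to the low-variability NS regime [0, 0.15].  The default 0.01
        (sd 8 ms) is the residual short-term variability left after the
        respiratory modulation is accounted for.
    mod_amp, mod_period
        Amplitude (s) and period (beats) of the slow modulation; the
        defaults (0.05 s over 6 beats) mimic respiratory sinus
        arrhythmia at rest, 75 bpm over ~12.5 breaths/min.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if not 0 <= cv <= 0.15:
        raise ValueError("NS regime requires cv in [0, 0.15]")
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    values = mean_rr + mod_amp * np.sin(2 * np.pi * t / mod_period)
    if cv > 0:
        values = values + rng.normal(0.0, cv * mean_rr, size=n)
    values = np.maximum(values, RR_MIN)
    return RRSeries(values, label="NS")


def generate_rr_af(
    n: int,
    mean_rr: float = 0.7,
    cv: float = 0.25,
    seed: int = 0,
) -> RRSeries:
    """Generate an atrial-fibrillation RR series.

    Intervals are i.i.d. gamma draws with the requested mean and CV,
    clipped to the physiologic range [0.2, 2.0] s.  The i.i.d. draw gives
    the defining AF signature: high variability with no serial
    correlation (lag-1 autocorrelation ~ 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if cv < 0.15:
        raise ValueError("AF regime requires cv >= 0.15")
    rng = np.random.default_rng(seed)
    shape = 1.0 / cv**2
    scale = mean_rr * cv**2
    values = np.clip(rng.gamma(shape, scale, size=n), RR_MIN, RR_MAX)
    return RRSeries(values, label="AF")


def synthesize_ecg(
    rr: RRSeries,
    cfg: SyntheticECGConfig = SyntheticECGConfig(),
    seed: int = 0,
) -> Tuple[Signal, np.ndarray]:
    """Synthesize a single-lead PQRST waveform from an RR series.

    Each beat is a sum of gaussian bumps (P, Q, R, S, T) centred relative
    to its R peak; n intervals produce n+1 beats.  Returns the uniformly
    sampled signal and the ground-truth R-peak sample indices.
    """
    fs = cfg.sampling_rate
    # R-peak times: lead-in, then cumulative RR.
    r_times = LEAD_IN_S + np.concatenate([[0.0], np.cumsum(rr.values)])
    duration = r_times[-1] + LEAD_IN_S
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    # local beat length at each R: mean of adjacent intervals
    intervals = rr.values
    for i, rt in enumerate(r_times):
        left = intervals[i - 1] if i > 0 else intervals[0]
        right = intervals[i] if i < len(intervals) else intervals[-1]
        beat_len = 0.5 * (left + right)
        for wave in cfg.wave_params.values():
            centre = rt + wave.center * beat_len
            x += wave.amplitude * np.exp(-0.5 * ((t - centre) / wave.width) ** 2)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, cfg.noise_sd, size=n_samples)
    peak_indices = np.round(r_times * fs).astype(int)
    return Signal(x, fs), peak_indices


def _draw_grid(img: np.ndarray, cfg: ChartRenderConfig) -> None:
    """Paint fine and bold grid lines in place (bold lines 2 px wide)."""
    h, w, _ = img.shape
    fine_px = cfg.fine_grid_mm * cfg.px_per_mm
    bold_px = cfg.bold_grid_mm * cfg.px_per_mm
    color = np.asarray(cfg.grid_color, dtype=np.uint8)
    for step, thick in ((fine_px, 1), (bold_px, 2)):
        cols = np.round(np.arange(0, w, step)).astype(int)
        rows = np.round(np.arange(0, h, step)).astype(int)
        for c in cols:
            img[:, max(c - thick + 1, 0) : c + 1] = color
        for r in rows:
            img[max(r - thick + 1, 0) : r + 1, :] = color


def render_chart(
    signal: Signal,
    cfg: ChartRenderConfig = ChartRenderConfig(),
    seed: int = 0,
) -> np.ndarray:
    """Render a signal as a gridded ECG chart image (RGB uint8 array).

    The trace is drawn one column per horizontal pixel; between adjacent
    columns the full vertical span is filled so steep QRS flanks appear as
    the solid vertical pixel runs a real printout shows.  Pixel scaling is
    dpi*paper_speed/25.4 px per second and dpi*gain/25.4 px per mV.
    """
    if signal.samples.size == 0:
        raise ValueError("cannot render an empty signal")
    width = int(np.ceil(signal.duration * cfg.px_per_second))
    height = int(round(cfg.height_mm * cfg.px_per_mm))
    img = np.full((height, width, 3), 255, dtype=np.uint8)
    _draw_grid(img, cfg)

    # baseline placed at 2/3 height so negative S waves stay on-strip
    baseline_row = int(round(height * 2 / 3))
    # per-column amplitude by linear interpolation of the signal
    col_t = (np.arange(width) + 0.5) / cfg.px_per_second
    amp = np.interp(col_t, signal.times, signal.samples)
    rows = baseline_row - np.round(amp * cfg.px_per_mv).astype(int)
    rows = np.clip(rows, 0, height - 1)

    color = np.asarray(cfg.trace_color, dtype=np.uint8)
    for c in range(width):
        r = rows[c]
        if c > 0:
            lo, hi = sorted((rows[c - 1], r))
        else:
            lo = hi = r
        img[lo : hi + 1, c] = color

    if cfg.speck_noise_rate > 0:
        rng = np.random.default_rng(seed)
        n_specks = int(cfg.speck_noise_rate * height * width)
        rs = rng.integers(0, height, n_specks)
        cs = rng.integers(0, width, n_specks)
        img[rs, cs] = np.where(rng.random((n_specks, 1)) < 0.5, 0, 255)
    return img


def save_chart(img: np.ndarray, path: str | Path, dpi: float = 600.0) -> Path:
    """Write a rendered chart as PNG or single-page PDF (by extension)."""
    path = Path(path)
    pil = Image.fromarray(img, mode="RGB")
    if path.suffix.lower() == ".pdf":
        pil.save(path, format="PDF", resolution=dpi)
    else:
        pil.save(path, dpi=(dpi, dpi))
    return path


def save_rr_csv(rr: RRSeries, path: str | Path, header: bool = True) -> Path:
    """Write an RR series as a one-column CSV of seconds."""
    path = Path(path)
    lines = (["rr_s"] if header else []) + [f"{v:.6f}" for v in rr.values]
    path.write_text("\n".join(lines) + "\n")
    return path


def load_rr_csv(path: str | Path) -> RRSeries:
    """Read an RR series from CSV (one interval per line, optional header)."""
    rows: List[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip().split(",")[0]
        if not line:
            continue
        try:
            rows.append(float(line))
        except ValueError:
            continue  # header token
    return RRSeries(np.asarray(rows))


def save_peaks_sidecar(peaks: np.ndarray, sampling_rate: float, path: str | Path) -> Path:
    """Write ground-truth R-peak indices as a JSON sidecar."""
    path = Path(path)
    path.write_text(
        json.dumps({"r_peak_indices": [int(p) for p in peaks], "sampling_rate": sampling_rate})
    )
    return path
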